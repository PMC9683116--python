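"""Cortical linescan, peak breadth and furrow enrichment on one cell.

Simulates a dividing cell, preprocesses the movie (ROI background
subtraction, ratio bleach correction, 2-central-slice projection),
extracts the five-pixel-wide pole-to-pole linescan at furrow onset,
registers it to the furrow and measures breadth and enrichment.
"""

from ringmetrics import (
    CortexPath,
    FurrowLine,
    QuantConfig,
    SimParams,
    extract_cortical_linescan,
    furrow_enrichment,
    normalize_profile,
    peak_breadth,
    preprocess_movie,
    register_to_furrow,
    simulate_division_movie,
)

params = SimParams(seed=1)
movie, truth = simulate_division_movie(params)
_, plane = preprocess_movie(movie, background_method="roi", roi=(0, 24, 0, 24))

t = params.ingression_start_frame  # furrow onset
profile = extract_cortical_linescan(
    plane, CortexPath(truth.cortex_path[t], frame_index=t)
)
profile = register_to_furrow(profile, FurrowLine(truth.furrow_line[t], frame_index=t))
profile = normalize_profile(profile)

cfg50 = QuantConfig(breadth_cutoff_fraction=0.5)
cfg75 = QuantConfig(breadth_cutoff_fraction=0.75)
b50 = peak_breadth(profile, cfg50)
b75 = peak_breadth(profile, cfg75)
enrich = furrow_enrichment(profile, b75, cfg75)

print(f"samples along cortex:   {len(profile)}")
print(f"baseline (polar) level: {profile.baseline:.1f} a.u.")
print(f"peak height:            {profile.peak_height:.1f} a.u.")
print(f"breadth @50% cutoff:    {b50.breadth_um:.2f} um "
      f"(generative truth {truth.true_breadth_um:.2f} um)")
print(f"breadth @75% cutoff:    {b75.breadth_um:.2f} um")
print(f"furrow/pole enrichment: {enrich.enrichment_ratio:.2f}-fold "
      f"(generative fold {truth.true_enrichment_fold})")
# Breadth is the contiguous run of cortex above the cutoff around the
# peak; enrichment divides the mean intensity in that run by the polar
# 50-pixel window mean. Both are ratios of preprocessed intensities, so
# they are independent of exposure and bleaching.
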