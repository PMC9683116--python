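"""Ground-truth recovery harness.

Runs the full measurement pipeline on simulated dividing cells and
compares every estimate with the generative truth. Used by the test
suite and by the reproduction script, and handy for sanity-checking
parameter changes.

The background is estimated from a corner region outside the cell (the
ROI method): under zero-mean noise the ROI mean is an unbiased estimate
of the background, whereas a low-percentile estimate is biased low by
construction.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .config import QuantConfig
from .linescan import CortexPath, FurrowLine, extract_cortical_linescan, normalize_profile, register_to_furrow
from .metrics import cortex_cytosol_ratio, furrow_enrichment, ingression_duration, peak_breadth
from .preprocess import preprocess_movie
from .simulate import GroundTruth, SimParams, ring_outlines_from_truth, simulate_division_movie
from .symmetry import fit_circle, normalize_trajectory, symmetry_value

__all__ = ["measure_simulated_cell", "recovery_study", "measure_metaphase_ratio"]

_BACKGROUND_ROI = (0, 24, 0, 24)  # corner region outside the default cell


def measure_simulated_cell(
    params: SimParams,
    config: QuantConfig | None = None,
    enrichment_cutoff: float = 0.75,
    outline_noise_px: float = 0.5,
) -> dict:
    """Simulate one cell and run every estimator against its ground truth.

    Breadth is measured at the 50 % cutoff (its truth is the analytic
    band width at half maximum); enrichment over the breadth region at
    ``enrichment_cutoff`` (the cross-cell-line convention). The linescan
    is taken at the furrow-onset frame using the simulator's cortex path
    and furrow line as the manual annotations they stand in for.
    """
    config = config or QuantConfig()
    cfg50 = QuantConfig(**{**config.to_dict(), "breadth_cutoff_fraction": 0.5,
                           "end_on_roi_px": config.end_on_roi_px})
    cfg_en = QuantConfig(**{**config.to_dict(), "breadth_cutoff_fraction": enrichment_cutoff,
                            "end_on_roi_px": config.end_on_roi_px})
    movie, truth = simulate_division_movie(params)
    _, plane = preprocess_movie(
        movie, n_central_slices=2, background_method="roi", roi=_BACKGROUND_ROI
    )
    t = params.ingression_start_frame
    profile = extract_cortical_linescan(
        plane,
        CortexPath(truth.cortex_path[t], width_px=config.linescan_width_px, frame_index=t),
        pole_window_px=config.pole_window_px,
    )
    profile = register_to_furrow(profile, FurrowLine(truth.furrow_line[t], frame_index=t))
    profile = normalize_profile(profile, baseline_mode=config.baseline_mode)

    breadth = peak_breadth(profile, cfg50)
    breadth_en = peak_breadth(profile, cfg_en)
    enrich = furrow_enrichment(profile, breadth_en, cfg_en)

    outlines = ring_outlines_from_truth(truth, noise_px=outline_noise_px, seed=params.seed)
    fits = [fit_circle(outlines[k], radius_rule=config.circle_radius_rule)
            for k in sorted(outlines)]
    sym = symmetry_value(normalize_trajectory(fits))

    ingress = ingression_duration(
        truth.furrow_width_trace_px(), truth.anaphase_frame,
        params.frame_interval_min, config,
    )

    return {
        "seed": params.seed,
        "breadth_um": breadth.breadth_um,
        "true_breadth_um": truth.true_breadth_um,
        "enrichment": enrich.enrichment_ratio,
        "true_enrichment": truth.true_enrichment_fold,
        "symmetry": sym,
        "true_symmetry": truth.true_symmetry_value,
        "duration_min": ingress.duration_min,
        "true_duration_min": truth.true_ingression_duration_min,
    }


def measure_metaphase_ratio(params: SimParams) -> dict:
    """Cortex/cytosol ratio of a metaphase cell (no equatorial band yet).

    The full cortex is scanned along a circle of the cell radius and the
    cytosol is averaged over a central region of interest, both on the
    first (pre-anaphase) frame.
    """
    movie, truth = simulate_division_movie(params)
    _, plane = preprocess_movie(
        movie, n_central_slices=2, background_method="roi", roi=_BACKGROUND_ROI
    )
    ny, nx = params.image_shape
    cy, cx = (ny - 1) / 2.0, (nx - 1) / 2.0
    r_px = params.cell_radius_um / params.pixel_size_um
    theta = np.linspace(0, 2 * np.pi, 256)
    circle = np.column_stack([cx + r_px * np.cos(theta), cy + r_px * np.sin(theta)])
    profile = extract_cortical_linescan(plane, CortexPath(circle, frame_index=0))
    half = int(0.3 * r_px)
    cytosol = float(plane.data[0, int(cy) - half : int(cy) + half,
                               int(cx) - half : int(cx) + half].mean())
    result = cortex_cytosol_ratio(profile, cytosol)
    return {
        "cortex_cytosol_ratio": result.cortex_cytosol_ratio,
        "true_cortex_cytosol_ratio": truth.true_cortex_cytosol_ratio,
    }


def recovery_study(
    seeds,
    base_params: SimParams | None = None,
    closure_asymmetry: float = 0.5,
) -> pd.DataFrame:
    """Run :func:`measure_simulated_cell` across seeds; one row per cell."""
    base = base_params or SimParams()
    rows = []
    for seed in seeds:
        params = SimParams.from_dict(
            {**base.to_dict(), "seed": int(seed), "closure_asymmetry": closure_asymmetry}
        )
        rows.append(measure_simulated_cell(params))
    return pd.DataFrame(rows)
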