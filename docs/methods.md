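# Methods

This note documents the measurement model, the synthetic-data generator,
the numerical conventions and the design choices behind `ringmetrics`.

## Measurement model

All quantities are computed on preprocessed movies: background is
subtracted per frame (clamped at zero), frames are rescaled for
photobleaching, and the two (cortical work) or six (central-spindle
work) central Z slices are averaged into a plane. Intensities are kept
as floating point throughout. Coordinates are 0-based `(x, y)` pixels
with y increasing downward; physical calibration (µm/pixel, µm/slice,
min/frame) must be supplied explicitly — there are no silent defaults
for physical units.

**Linescan.** A cortical profile samples the projected plane at one-pixel
arc spacing along a user-traced pole-to-pole polyline. Each sample is
the mean of `width_px` (default 5, odd) bilinear sub-samples placed
perpendicular to the local path direction, reproducing the behaviour of
a wide ImageJ line selection; sub-samples falling outside the image are
dropped from the mean. The sample count is `round(arc length) + 1`.
Samples are positioned relative to the furrow as the signed arc distance
from the path's intersection with a user-traced furrow segment (nearest
approach within 10 px when they do not intersect exactly).

**Normalization.** The baseline is the mean of a 50-sample window at one
end of the scan. Because "first or last" is ambiguous when one pole abuts
a neighbouring cell, the default takes the dimmer of the two windows
(`baseline_mode="min"`); averaging both is available. The peak is the
global maximum, with ties resolved to the lowest arc position for
determinism; `peak_height = max − baseline`.

**Breadth.** The cutoff is applied to baseline-referenced intensity,
`cutoff = baseline + c · peak_height`, with samples exactly at the
cutoff counting as above it. The breadth is the length of the maximal
contiguous above-cutoff run containing the peak; above-cutoff samples
outside that run (e.g. a bright neighbouring structure crossing the
scan) are excluded and tallied separately. The 50 % cutoff is the
convention for comparing different proteins, whose peak intensities
differ widely; 75 % for comparing one protein across cell lines. The
breadth is reported in pixels, µm, and as a fraction of the cortical
length to control for cell size.

**Enrichment.** Furrow/pole enrichment divides the mean raw intensity
over the breadth region by the polar-window mean (same window convention
as the baseline). Note this is a *regional mean* ratio: for a Gaussian
band of peak fold `f` and width σ measured over its own width at cutoff
`c`, the expected ratio is `1 + (f − 1) · g(c)` with
`g(0.5) ≈ 0.81` and `g(0.75) ≈ 0.91` (the mean of a Gaussian over its
central above-`c` interval). Regional means are robust to single-pixel
noise, at the cost of sitting systematically below the peak fold; the
recovery tests account for this by measuring the enrichment over the
75 % region. Both breadth and enrichment are invariant under
multiplicative intensity scaling (exposure, bleaching); enrichment is
deliberately *not* invariant under additive offsets, which is why
background subtraction precedes it.

**Ingression duration.** Duration runs from anaphase onset to the first
frame whose furrow width is at or below `closure_width_px` (default
1 px), times the frame interval. Traces that never reach the threshold
are flagged "not closed" and excluded from duration statistics rather
than aborting a batch. Furrow width traces are inputs (from annotation
or simulator truth); automated furrow tracking is out of scope.

**Ring-closure symmetry.** Ring outlines — manually drawn point sets
(≥ 5) or ellipse parameters — are fit with a direct least-squares
ellipse and reduced to a best-fit circle: centre = ellipse centre,
radius = (a + b)/2 by default (√(ab) available). Trajectories are
normalized so the first timepoint has centre (0, 0) and radius 1; the
symmetry value is the Euclidean norm of the last normalized centre.
Only the endpoints enter the score; intermediate timepoints inform
plots and QC only. Classification: < 0.2 symmetric, > 0.6 highly
asymmetric, boundaries inclusive into the middle (asymmetric) class —
the published prose ("less than 0.2", "between 0.2 and 0.6", "greater
than 0.6") leaves exact boundaries open, so the convention is stated
once here and used everywhere. The end-on view is produced by linearly
interpolating Z into an in-plane axis scaled by the
`z_step / pixel_size` anisotropy factor over a user-chosen region
(default 50 × 250 px).

## Synthetic-data generator

The phantom emulates the rounded mitotic cells of high-magnification
confocal time-lapse imaging: a surface-of-revolution cell (sphere of
radius `cell_radius_um`, default 10 µm) whose cortical shell
(`cortex_thickness_um`, 1 µm) carries intensity `cortex_level`
multiplied, from `enrichment_onset_frame` onward, by a Gaussian band in
meridian arc length centred on the equator
(`1 + (fold − 1) · exp(−s²/2σ²)`); the interior carries
`cytosol_level`. From `ingression_start_frame` the equatorial
cross-section radius shrinks linearly at `ingression_rate_um_per_min`
(pinch profile Gaussian in y with the band's σ), and the ring centre
drifts toward one side by `closure_asymmetry × R × progress`, reaching
`closure_asymmetry × R` at closure — a linear drift toward a fixed
cortical point, the simplest model reproducing one-sided ingression.
Frames are multiplied by `(1 − bleach_rate)^t`, offset by a constant
background, then noised (Gaussian of fixed σ, or Poisson treating the
a.u. value as the expected count). Identical parameters, including the
seed, give bit-identical output.

Rendering uses a signed-distance field: the per-row cross-section
distance is normalized by the meridian slope (`1/√(1 + ρ′²)`) so the
shell has uniform thickness along the surface normal, with the exact
spherical distance used in the polar caps where the slope diverges.
Shell edges ramp linearly over two pixels (partial-volume
anti-aliasing, a coarse stand-in for optical blur). Without this the
rasterized shell produces ~10 % sampling ripple along a nominally
uniform cortex; with it, a fold-1 cortex profile is flat to ~1.5 %.

Defaults are the study conditions: 160×160 px at 0.2 µm/px, 8 slices of
1 µm, 20 frames at 1 min (within the 1–2 min acquisition convention;
the finer interval also bounds the truncation of the symmetry value,
since the last outlinable ring — radius ≥ 2 px — is then ~94 % closed),
8-fold enrichment with σ = 2 µm, ingression from frame 2 at
0.625 µm/min (16 min closure), 2 % bleaching/frame, background 50 a.u.,
Gaussian noise σ = 15 a.u. (5 % of the 300 a.u. cortex). Eight slices
put the two central slices symmetrically at ±0.5 µm about the cell
centre; an odd count leaves them straddling −1/0 µm, which drops the
polar cortex out of one slice and biases pole means low. The true band
width at cutoff `c` is `2σ√(2 ln(1/c))` (4.71 µm at 50 %). The
generator's anaphase onset coincides with `ingression_start_frame`.

What the phantom does **not** model: point-spread blur beyond the 2 px
edge ramp, camera gain/offset structure, cortical flows and ruffling,
neighbouring cells, central-spindle or astral signals, and any
cell-line-specific measured values. Passing recovery tests therefore
demonstrates estimator correctness on idealized geometry with realistic
sampling, noise and bleaching — not performance on real micrographs,
where manual tracing quality dominates.

## Numerical choices and degenerate inputs

- Background percentile default 5 %: parameter-free and robust while the
  cell occupies a minority of the field, but biased low by ≈ 1.645 σ
  under Gaussian noise; the background-ROI method is unbiased and is
  what the validation harness uses. The choice is logged per movie.
- Ratio bleach correction forces every frame mean to the first frame's,
  which also flattens genuine intensity changes (band assembly,
  volume loss during ingression); all downstream metrics are intensity
  ratios and are unaffected. The exponential fit preserves such changes
  and is preferred when absolute intensities matter.
- Central-slice blocks start at `floor((Z − n)/2)`.
- Sub-pixel sampling is bilinear everywhere (`map_coordinates`,
  order 1).
- Ellipse fits require ≥ 5 non-collinear points; exact circles trigger a
  harmless 0/0 in the (irrelevant) orientation angle, silenced locally.
- Profiles shorter than two pole windows plus one sample, zero cytosol
  or pole means, zero first-frame means, and cells larger than the
  image are all rejected with specific messages.
- Group SD uses the n−1 convention; single-observation groups report
  SD 0 with an explicit flag.

## Validation harness and problem sizes

`ringmetrics.validation` simulates cells at the default conditions and
runs the complete pipeline — preprocess, linescan at the furrow-onset
frame using the simulator's cortex path and furrow line as stand-ins
for manual annotations, breadth at 50 %, enrichment over the 75 %
region, symmetry from noisy 12-point outlines of the true rings
(0.5 px jitter), duration from the true width trace. Across 20 seeds
this recovers breadth within ~3 %, enrichment within ~11 % (the
regional-mean systematic discussed above), symmetry within ~0.03
absolute, and duration exactly, comfortably inside the 15 % / 0.05 /
one-frame tolerances the tests assert. Twenty seeds at the default
160×160×8×20 problem size run in a few seconds; the suite and the
reproduction script each finish in well under a minute on one CPU.

## Known limitations

- Cortex paths, furrow lines and ring outlines are inputs; no
  segmentation, tracing or ring detection is provided, matching the
  manual workflow the measurements come from.
- The symmetry value depends on the last *measured* timepoint: coarse
  frame intervals truncate it toward zero because the final ring cannot
  be outlined. This is a property of the measurement, not the code.
- Poisson noise treats arbitrary units as expected counts; real
  EMCCD statistics (gain, excess noise) are not modelled.
- The statistical layer stops at descriptive n/mean/SD summaries;
  hypothesis testing belongs to downstream analysis tools.
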