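"""Per-cell contractile-ring statistics.

Breadth: the length of the maximal contiguous run of linescan samples
whose intensity exceeds ``baseline + cutoff_fraction * peak_height`` and
which contains the peak; isolated above-cutoff samples outside that run
are excluded (counted separately). Enrichment: mean raw intensity over
the breadth region divided by the polar-window mean. The metaphase
cortex/cytosol ratio, ingression duration and per-group descriptive
summaries complete the set.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import QuantConfig
from .linescan import LinescanProfile

__all__ = [
    "BreadthResult",
    "EnrichmentResult",
    "IngressionResult",
    "peak_breadth",
    "breadth_fraction",
    "furrow_enrichment",
    "cortex_cytosol_ratio",
    "ingression_duration",
    "summarize_groups",
]


@dataclass(frozen=True)
class BreadthResult:
    breadth_px: int
    breadth_um: float
    breadth_fraction: float
    cutoff_fraction: float
    peak_region: tuple[int, int]  # half-open [start, stop) sample range
    excluded_pixel_count: int


@dataclass(frozen=True)
class EnrichmentResult:
    furrow_mean: float | None = None
    pole_mean: float | None = None
    enrichment_ratio: float | None = None
    cortex_mean: float | None = None
    cytosol_mean: float | None = None
    cortex_cytosol_ratio: float | None = None


@dataclass(frozen=True)
class IngressionResult:
    closed: bool
    closure_frame: int | None
    duration_min: float | None


def _pole_mean(profile: LinescanProfile) -> float:
    """Polar-window mean, following the profile's baseline convention."""
    w = profile.pole_window_px
    first = float(np.mean(profile.intensity[:w]))
    last = float(np.mean(profile.intensity[-w:]))
    mode = profile.baseline_mode or "min"
    return min(first, last) if mode == "min" else 0.5 * (first + last)


def peak_breadth(profile: LinescanProfile, config: QuantConfig) -> BreadthResult:
    """Width of the equatorial peak at the configured cutoff.

    The cutoff is applied to baseline-referenced intensity
    (``baseline + fraction * peak_height``); samples exactly at the cutoff
    count as above it. Only the contiguous above-cutoff run containing the
    peak contributes to the breadth; other above-cutoff samples are
    tallied in ``excluded_pixel_count``.
    """
    if not profile.is_normalized:
        raise ValueError("profile must be normalized first (see normalize_profile)")
    if profile.peak_height is None or profile.peak_height <= 0:
        raise ValueError("no measurable peak: peak_height <= 0")
    cutoff = profile.baseline + config.breadth_cutoff_fraction * profile.peak_height
    above = profile.intensity >= cutoff
    peak = profile.peak_index
    start = peak
    while start > 0 and above[start - 1]:
        start -= 1
    stop = peak + 1
    while stop < len(above) and above[stop]:
        stop += 1
    breadth_px = stop - start
    excluded = int(above.sum()) - breadth_px
    return BreadthResult(
        breadth_px=breadth_px,
        breadth_um=breadth_px * profile.pixel_size_um,
        breadth_fraction=breadth_px / len(profile),
        cutoff_fraction=config.breadth_cutoff_fraction,
        peak_region=(start, stop),
        excluded_pixel_count=excluded,
    )


def breadth_fraction(result: BreadthResult, total_samples: int) -> float:
    """Breadth as a ratio of cortical length, controlling for cell size."""
    if total_samples <= 0:
        raise ValueError("total_samples must be > 0")
    if total_samples < result.breadth_px:
        raise ValueError("total_samples cannot be smaller than the breadth")
    return result.breadth_px / total_samples


def furrow_enrichment(
    profile: LinescanProfile, breadth: BreadthResult, config: QuantConfig
) -> EnrichmentResult:
    """Furrow-vs-pole enrichment: mean raw intensity over the breadth
    region divided by the polar-window mean (same window convention as the
    baseline)."""
    start, stop = breadth.peak_region
    furrow_mean = float(np.mean(profile.intensity[start:stop]))
    pole_mean = _pole_mean(profile)
    if pole_mean <= 0:
        raise ValueError("pole mean is <= 0; cannot form an enrichment ratio")
    return EnrichmentResult(
        furrow_mean=furrow_mean,
        pole_mean=pole_mean,
        enrichment_ratio=furrow_mean / pole_mean,
    )


def cortex_cytosol_ratio(
    cortex_profile: LinescanProfile, cytosol_region_mean: float
) -> EnrichmentResult:
    """Metaphase cortical enrichment: mean intensity of a linescan drawn
    around the full cortex over the mean of a cytosolic region."""
    if cytosol_region_mean <= 0:
        raise ValueError("cytosol mean must be > 0")
    cortex_mean = float(np.mean(cortex_profile.intensity))
    return EnrichmentResult(
        cortex_mean=cortex_mean,
        cytosol_mean=float(cytosol_region_mean),
        cortex_cytosol_ratio=cortex_mean / cytosol_region_mean,
    )


def ingression_duration(
    furrow_width_trace: np.ndarray,
    anaphase_frame: int,
    frame_interval_min: float,
    config: QuantConfig,
) -> IngressionResult:
    """Minutes from anaphase onset until the membrane is fully closed.

    Closure is the first frame (at or after anaphase onset) whose furrow
    width drops to ``config.closure_width_px`` or below; a trace that
    never reaches the threshold is flagged as not closed, with no duration.
    """
    trace = np.asarray(furrow_width_trace, dtype=float)
    if trace.ndim != 1 or len(trace) == 0:
        raise ValueError("furrow_width_trace must be a non-empty 1-D array")
    if np.any(trace < 0):
        raise ValueError("furrow widths must be non-negative")
    if not 0 <= anaphase_frame < len(trace):
        raise ValueError("anaphase_frame must index into the trace")
    closed = np.nonzero(trace[anaphase_frame:] <= config.closure_width_px)[0]
    if len(closed) == 0:
        return IngressionResult(closed=False, closure_frame=None, duration_min=None)
    closure_frame = anaphase_frame + int(closed[0])
    duration = (closure_frame - anaphase_frame) * frame_interval_min
    return IngressionResult(closed=True, closure_frame=closure_frame, duration_min=duration)


def summarize_groups(
    per_cell_table: pd.DataFrame,
    group_col: str = "cell_line",
    value_col: str = "value",
) -> pd.DataFrame:
    """Descriptive n / mean / sample-SD per group, as a tidy table.

    Groups with a single observation report SD 0 and are flagged in the
    ``single_observation`` column.
    """
    if len(per_cell_table) == 0:
        raise ValueError("empty table")
    rows = []
    for group, sub in per_cell_table.groupby(group_col, sort=True):
        values = sub[value_col].to_numpy(dtype=float)
        n = len(values)
        rows.append(
            {
                group_col: group,
                "n": n,
                "mean": float(np.mean(values)),
                "sd": float(np.std(values, ddof=1)) if n > 1 else 0.0,
                "single_observation": n == 1,
            }
        )
    return pd.DataFrame(rows)
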