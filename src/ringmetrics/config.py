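"""Quantification configuration shared across the measurement stages."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass


@dataclass(frozen=True)
class QuantConfig:
    """Thresholds and conventions used by the measurement operations.

    Parameters
    ----------
    breadth_cutoff_fraction:
        Fraction of the baseline-referenced peak height above which cortical
        samples count toward the breadth. 0.5 is used to compare different
        proteins (accommodating weak peaks such as RhoA); 0.75 to compare the
        same protein across cell lines.
    pole_window_px:
        Number of samples at each end of a pole-to-pole linescan treated as
        polar cortex, used both for the baseline and the enrichment denominator.
    linescan_width_px:
        Width (odd, in pixels) of the cortical linescan band.
    symmetric_cutoff, high_asym_cutoff:
        Boundaries on the ring-closure symmetry value separating symmetric
        (< symmetric_cutoff), asymmetric and highly asymmetric
        (> high_asym_cutoff) closure. Boundary values fall in the middle
        (asymmetric) class.
    end_on_roi_px:
        Default (height, width) of the region rotated to produce an end-on
        view of the closing ring.
    closure_width_px:
        Furrow width at or below which the membrane is considered fully
        closed when measuring ingression duration.
    baseline_mode:
        "min" uses the dimmer of the two pole windows as baseline (robust when
        one pole abuts a neighbouring cell); "both" averages the two windows.
    circle_radius_rule:
        Reduction from a fitted ellipse to a best-fit circle radius:
        "mean" -> (a + b) / 2, "geometric" -> sqrt(a * b).
    """

    breadth_cutoff_fraction: float = 0.5
    pole_window_px: int = 50
    linescan_width_px: int = 5
    symmetric_cutoff: float = 0.2
    high_asym_cutoff: float = 0.6
    end_on_roi_px: tuple[int, int] = (50, 250)
    closure_width_px: float = 1.0
    baseline_mode: str = "min"
    circle_radius_rule: str = "mean"

    def __post_init__(self) -> None:
        if not 0.0 < self.breadth_cutoff_fraction < 1.0:
            raise ValueError("breadth_cutoff_fraction must lie in (0, 1)")
        if self.pole_window_px < 1:
            raise ValueError("pole_window_px must be >= 1")
        if self.linescan_width_px < 1 or self.linescan_width_px % 2 == 0:
            raise ValueError("linescan_width_px must be odd and >= 1")
        if not 0.0 < self.symmetric_cutoff < self.high_asym_cutoff:
            raise ValueError("need 0 < symmetric_cutoff < high_asym_cutoff")
        if self.closure_width_px < 0:
            raise ValueError("closure_width_px must be >= 0")
        if self.baseline_mode not in ("min", "both"):
            raise ValueError("baseline_mode must be 'min' or 'both'")
        if self.circle_radius_rule not in ("mean", "geometric"):
            raise ValueError("circle_radius_rule must be 'mean' or 'geometric'")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["end_on_roi_px"] = list(self.end_on_roi_px)
        return d

    def hash(self) -> str:
        """Short stable digest of the configuration, for output provenance."""
        payload = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]

    @classmethod
    def from_dict(cls, d: dict) -> "QuantConfig":
        d = dict(d)
        if "end_on_roi_px" in d:
            d["end_on_roi_px"] = tuple(d["end_on_roi_px"])
        return cls(**d)
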