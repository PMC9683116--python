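"""In-memory containers for calibrated time-lapse Z-stack movies."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class Movie:
    """A T x Z x Y x X fluorescence movie with physical calibration.

    Intensities are arbitrary units (a.u.) and kept as floating point after
    any preprocessing step, even when the source TIFF was integer. Coordinates
    follow the image convention used throughout this package: 0-based,
    (row, column) = (y, x), with y increasing downward.
    """

    data: np.ndarray
    pixel_size_um: float
    z_step_um: float
    frame_interval_min: float
    channel_name: str = ""
    axis_order: str = "TZYX"
    log: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 4:
            raise ValueError(
                f"movie data must be 4-D (T, Z, Y, X); got shape {self.data.shape}"
            )
        if min(self.data.shape) < 1:
            raise ValueError("all movie dimensions must be >= 1")
        if self.pixel_size_um <= 0 or self.z_step_um <= 0:
            raise ValueError("pixel_size_um and z_step_um must be > 0")
        if self.frame_interval_min <= 0:
            raise ValueError("frame_interval_min must be > 0")
        if self.axis_order != "TZYX":
            raise ValueError("in-memory movies are always TZYX; reorder on read")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("movie intensities must be finite")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def n_slices(self) -> int:
        return self.data.shape[1]

    @property
    def shape(self) -> tuple:
        return self.data.shape


@dataclass
class PlaneSeries:
    """A T x Y x X projected series with the projection provenance recorded."""

    data: np.ndarray
    provenance: str
    pixel_size_um: float
    frame_interval_min: float
    channel_name: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError("plane series data must be 3-D (T, Y, X)")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]
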