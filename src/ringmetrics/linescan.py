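"""Cortical and midzone linescan extraction, furrow registration and
baseline normalization.

A linescan samples a preprocessed plane at one-pixel arc-length spacing
along a pole-to-pole polyline traced on the cortex (or a straight line
across the midzone). Each sample is the mean of ``width_px`` bilinear
sub-samples placed perpendicular to the local path direction, matching
the behaviour of a wide ImageJ line selection. Samples are positioned
relative to the furrow crossing, and the profile is normalized against
the polar baseline: the average of the first or last ``pole_window_px``
samples (the dimmer window by default).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage
from shapely.geometry import LineString
from shapely.ops import nearest_points

from .movie import PlaneSeries

__all__ = [
    "CortexPath",
    "FurrowLine",
    "LinescanProfile",
    "extract_cortical_linescan",
    "extract_midzone_linescan",
    "register_to_furrow",
    "normalize_profile",
]


@dataclass
class CortexPath:
    """Ordered (x, y) vertices of a pole-to-pole cortical polyline."""

    vertices: np.ndarray
    width_px: int = 5
    frame_index: int = 0

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 2:
            raise ValueError("vertices must be an (N, 2) array of (x, y)")
        if len(self.vertices) < 2:
            raise ValueError("a path needs at least 2 vertices")
        if np.any(np.all(np.diff(self.vertices, axis=0) == 0, axis=1)):
            raise ValueError("consecutive vertices must be distinct")
        if self.width_px < 1 or self.width_px % 2 == 0:
            raise ValueError("width_px must be odd and >= 1")

    def reversed(self) -> "CortexPath":
        return CortexPath(self.vertices[::-1].copy(), self.width_px, self.frame_index)


@dataclass
class FurrowLine:
    """A straight one-pixel-wide segment intersecting the furrow."""

    endpoints: np.ndarray
    frame_index: int = 0

    def __post_init__(self) -> None:
        self.endpoints = np.asarray(self.endpoints, dtype=float)
        if self.endpoints.shape != (2, 2):
            raise ValueError("endpoints must be a (2, 2) array of (x, y)")
        if np.all(self.endpoints[0] == self.endpoints[1]):
            raise ValueError("furrow endpoints must be distinct")


@dataclass
class LinescanProfile:
    """Ordered cortical samples with optional furrow registration and
    baseline normalization metadata.

    ``baseline``, ``peak_height`` and ``peak_index`` are populated by
    :func:`normalize_profile`; the raw samples are never altered.
    """

    arc_position_px: np.ndarray
    intensity: np.ndarray
    furrow_offset_px: np.ndarray | None = None
    pixel_size_um: float = 1.0
    pole_window_px: int = 50
    baseline: float | None = None
    peak_height: float | None = None
    peak_index: int | None = None
    baseline_mode: str | None = None
    sample_xy: np.ndarray | None = field(default=None, repr=False)
    crossing_arc_px: float | None = None

    def __post_init__(self) -> None:
        self.arc_position_px = np.asarray(self.arc_position_px, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.arc_position_px.shape != self.intensity.shape:
            raise ValueError("arc_position_px and intensity must be equal length")
        if self.furrow_offset_px is not None:
            self.furrow_offset_px = np.asarray(self.furrow_offset_px, dtype=float)
            if self.furrow_offset_px.shape != self.intensity.shape:
                raise ValueError("furrow_offset_px must match the sample count")
        if np.any(np.diff(self.arc_position_px) <= 0):
            raise ValueError("samples must be ordered by increasing arc position")

    def __len__(self) -> int:
        return len(self.intensity)

    @property
    def is_normalized(self) -> bool:
        return self.baseline is not None and self.peak_height is not None

    def reversed(self) -> "LinescanProfile":
        """The same scan traversed from the opposite pole."""
        arc = self.arc_position_px[-1] - self.arc_position_px[::-1]
        return LinescanProfile(
            arc_position_px=arc,
            intensity=self.intensity[::-1].copy(),
            furrow_offset_px=None
            if self.furrow_offset_px is None
            else -self.furrow_offset_px[::-1],
            pixel_size_um=self.pixel_size_um,
            pole_window_px=self.pole_window_px,
            sample_xy=None if self.sample_xy is None else self.sample_xy[::-1].copy(),
        )


def _resample_polyline(vertices: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Sample a polyline at 1-px arc spacing; returns (arc, xy) arrays.

    The sample count is round(total arc length) + 1; the last sample is
    clamped to the path end when the length is not an integer.
    """
    seg = np.diff(vertices, axis=0)
    seglen = np.hypot(seg[:, 0], seg[:, 1])
    cum = np.concatenate([[0.0], np.cumsum(seglen)])
    total = cum[-1]
    n = int(round(total)) + 1
    arc = np.minimum(np.arange(n, dtype=float), total)
    x = np.interp(arc, cum, vertices[:, 0])
    y = np.interp(arc, cum, vertices[:, 1])
    return arc, np.column_stack([x, y])


def _profile_from_polyline(
    image: np.ndarray,
    vertices: np.ndarray,
    width_px: int,
    pixel_size_um: float,
    pole_window_px: int,
) -> LinescanProfile:
    arc, xy = _resample_polyline(vertices)
    # Unit tangent via central differences of the resampled points.
    tangent = np.gradient(xy, axis=0)
    norm = np.hypot(tangent[:, 0], tangent[:, 1])
    norm[norm == 0] = 1.0
    tangent /= norm[:, None]
    normal = np.column_stack([-tangent[:, 1], tangent[:, 0]])

    offsets = np.arange(width_px) - width_px // 2
    # (n_samples, width) sub-sample coordinates.
    pts = xy[:, None, :] + offsets[None, :, None] * normal[:, None, :]
    h, w = image.shape
    inside = (
        (pts[..., 0] >= 0) & (pts[..., 0] <= w - 1)
        & (pts[..., 1] >= 0) & (pts[..., 1] <= h - 1)
    )
    # map_coordinates takes (row, col) = (y, x).
    coords = np.stack([pts[..., 1].ravel(), pts[..., 0].ravel()])
    values = ndimage.map_coordinates(
        np.asarray(image, dtype=float), coords, order=1, mode="nearest"
    ).reshape(pts.shape[:2])
    values = np.where(inside, values, np.nan)
    if np.any(~inside.any(axis=1)):
        raise ValueError("a linescan sample fell entirely outside the image")
    intensity = np.nanmean(values, axis=1)
    return LinescanProfile(
        arc_position_px=arc,
        intensity=intensity,
        pixel_size_um=pixel_size_um,
        pole_window_px=pole_window_px,
        sample_xy=xy,
    )


def _resolve_frame(plane, frame_index: int, pixel_size_um: float | None):
    if isinstance(plane, PlaneSeries):
        return plane.data[frame_index], plane.pixel_size_um
    image = np.asarray(plane)
    if image.ndim != 2:
        raise ValueError("expected a PlaneSeries or a single 2-D image")
    return image, (pixel_size_um if pixel_size_um is not None else 1.0)


def extract_cortical_linescan(
    plane,
    path: CortexPath,
    pole_window_px: int = 50,
    pixel_size_um: float | None = None,
) -> LinescanProfile:
    """Five-pixel-wide (by default) intensity profile along the cortex.

    ``plane`` may be a :class:`PlaneSeries` (the frame is selected by
    ``path.frame_index``) or a single 2-D image. Perpendicular sub-samples
    falling outside the image are dropped from the per-sample mean.
    """
    image, px = _resolve_frame(plane, path.frame_index, pixel_size_um)
    return _profile_from_polyline(image, path.vertices, path.width_px, px, pole_window_px)


def extract_midzone_linescan(
    plane,
    line: FurrowLine,
    width_px: int = 1,
    pole_window_px: int = 50,
    pixel_size_um: float | None = None,
) -> LinescanProfile:
    """Straight linescan across the midzone (central-spindle region), with
    the furrow offset measured from the line midpoint."""
    image, px = _resolve_frame(plane, line.frame_index, pixel_size_um)
    profile = _profile_from_polyline(image, line.endpoints, width_px, px, pole_window_px)
    mid = profile.arc_position_px[-1] / 2.0
    profile.furrow_offset_px = profile.arc_position_px - mid
    profile.crossing_arc_px = mid
    return profile


def register_to_furrow(
    profile: LinescanProfile,
    furrow: FurrowLine,
    max_distance_px: float = 10.0,
) -> LinescanProfile:
    """Position the samples relative to the furrow crossing.

    The crossing is the intersection of the furrow segment with the sampled
    path; if they do not intersect exactly, the nearest approach is used,
    provided it is within ``max_distance_px``.
    """
    if profile.sample_xy is None:
        raise ValueError("profile carries no sample coordinates; extract it from an image")
    path_ls = LineString(profile.sample_xy)
    furrow_ls = LineString(furrow.endpoints)
    inter = path_ls.intersection(furrow_ls)
    if not inter.is_empty:
        point = inter.geoms[0] if hasattr(inter, "geoms") else inter
    else:
        point, _ = nearest_points(path_ls, furrow_ls)
        if point.distance(furrow_ls) > max_distance_px:
            raise ValueError(
                f"furrow line is farther than {max_distance_px} px from the path"
            )
    crossing_arc = path_ls.project(point)
    registered = replace(
        profile,
        furrow_offset_px=profile.arc_position_px - crossing_arc,
        crossing_arc_px=float(crossing_arc),
    )
    return registered


def normalize_profile(
    profile: LinescanProfile, baseline_mode: str = "min"
) -> LinescanProfile:
    """Set baseline, peak height and peak index on a copy of the profile.

    The baseline is the mean of a ``pole_window_px``-sample window at one
    end of the scan: the dimmer of the two windows by default
    (``baseline_mode="min"``), or the average of both (``"both"``). The
    peak is the global maximum; ties resolve to the lowest arc position.
    """
    if baseline_mode not in ("min", "both"):
        raise ValueError("baseline_mode must be 'min' or 'both'")
    w = profile.pole_window_px
    if len(profile) < 2 * w + 1:
        raise ValueError(
            f"profile has {len(profile)} samples; need more than two "
            f"{w}-sample pole windows"
        )
    first = float(np.mean(profile.intensity[:w]))
    last = float(np.mean(profile.intensity[-w:]))
    baseline = min(first, last) if baseline_mode == "min" else 0.5 * (first + last)
    peak_index = int(np.argmax(profile.intensity))
    peak_height = float(profile.intensity[peak_index] - baseline)
    return replace(
        profile,
        baseline=baseline,
        peak_height=peak_height,
        peak_index=peak_index,
        baseline_mode=baseline_mode,
    )
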