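"""Ring-closure symmetry analysis from end-on views.

The closing contractile ring is viewed face-on (after reslicing the
Z-stack), its outline is recorded per timepoint as points or an ellipse,
and a best-fit circle summarizes each outline. Trajectories are
normalized to the first timepoint (centre (0, 0), radius 1); the symmetry
value is the Euclidean distance between that origin and the last
measured ring centre. Values below 0.2 are symmetric, above 0.6 highly
asymmetric, and in between (inclusive) asymmetric.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from skimage.measure import EllipseModel

from .config import QuantConfig
from .movie import Movie

__all__ = [
    "RingOutline",
    "CircleFit",
    "RingTrajectory",
    "SymmetryResult",
    "CATEGORIES",
    "reslice_end_on",
    "fit_circle",
    "normalize_trajectory",
    "symmetry_value",
    "classify_symmetry",
    "summarize_symmetry_classes",
]

CATEGORIES = ("symmetric", "asymmetric", "highly_asymmetric")


@dataclass
class RingOutline:
    """Manual ring outline: >= 5 perimeter points, or ellipse parameters
    (center, semi-axes a >= b, orientation in radians)."""

    frame_index: int
    points: np.ndarray | None = None
    ellipse: tuple[tuple[float, float], float, float, float] | None = None

    def __post_init__(self) -> None:
        if (self.points is None) == (self.ellipse is None):
            raise ValueError("provide exactly one of points or ellipse parameters")
        if self.points is not None:
            self.points = np.asarray(self.points, dtype=float)
            if self.points.ndim != 2 or self.points.shape[1] != 2:
                raise ValueError("points must be an (N, 2) array of (x, y)")
            if len(self.points) < 5:
                raise ValueError("need at least 5 outline points")
        else:
            _, a, b, _ = self.ellipse
            if not a >= b > 0:
                raise ValueError("ellipse semi-axes must satisfy a >= b > 0")


@dataclass(frozen=True)
class CircleFit:
    frame_index: int
    center: tuple[float, float]
    radius: float
    residual: float = 0.0

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("circle radius must be > 0")


@dataclass
class RingTrajectory:
    """Ordered circle fits with first-frame normalization applied."""

    fits: list
    normalized_centers: np.ndarray  # (T, 2), first row (0, 0)
    normalized_radii: np.ndarray  # (T,), first entry 1


@dataclass(frozen=True)
class SymmetryResult:
    symmetry_value: float
    category: str


def reslice_end_on(
    movie: Movie,
    roi: tuple[int, int, int, int] | None = None,
    axis: str = "XZ",
) -> tuple[np.ndarray, float]:
    """Resample a region so Z becomes an in-plane axis (end-on view).

    ``roi`` is (y0, x0, height, width), defaulting to a centred 50 x 250
    region. For ``axis="XZ"`` the output has shape (T, height, Z', width):
    per frame, one end-on (z, x) slice for each row of the region, with Z
    linearly interpolated to isotropic pixels using the
    z_step / pixel_size anisotropy factor. ``axis="YZ"`` swaps the roles
    of rows and columns. Returns the stack and its (isotropic) pixel size
    in micrometres.
    """
    if movie.n_slices < 2:
        raise ValueError("cannot reslice a single-slice movie")
    factor = movie.z_step_um / movie.pixel_size_um
    if factor <= 0:
        raise ValueError("anisotropy factor must be > 0")
    t, z, h, w = movie.data.shape
    if roi is None:
        rh, rw = 50, 250
        rh, rw = min(rh, h), min(rw, w)
        y0 = (h - rh) // 2
        x0 = (w - rw) // 2
        roi = (y0, x0, rh, rw)
    y0, x0, rh, rw = roi
    if not (0 <= y0 and y0 + rh <= h and 0 <= x0 and x0 + rw <= w and rh > 0 and rw > 0):
        raise ValueError("roi must lie inside the image")
    sub = movie.data[:, :, y0 : y0 + rh, x0 : x0 + rw]
    if axis == "YZ":
        sub = np.swapaxes(sub, 2, 3)  # rows <-> columns
    elif axis != "XZ":
        raise ValueError("axis must be 'XZ' or 'YZ'")

    n_out = int(round((z - 1) * factor)) + 1
    zsrc = np.arange(n_out) / factor  # fractional source slice index
    zsrc = np.clip(zsrc, 0, z - 1)
    lo = np.floor(zsrc).astype(int)
    hi = np.minimum(lo + 1, z - 1)
    frac = (zsrc - lo)[None, :, None, None]
    # (T, Z', rows, cols) by linear interpolation between slices.
    interp = sub[:, lo] * (1.0 - frac) + sub[:, hi] * frac
    out = np.swapaxes(interp, 1, 2)  # (T, rows, Z', cols)
    return out, movie.pixel_size_um


def fit_circle(outline: RingOutline, radius_rule: str = "mean") -> CircleFit:
    """Best-fit circle of a ring outline.

    Point input is fit with a direct least-squares ellipse; the circle
    centre is the ellipse centre and the radius reduces the semi-axes by
    ``(a + b) / 2`` (default) or ``sqrt(a * b)``. The residual is the RMS
    radial misfit of the points about the circle.
    """
    if radius_rule not in ("mean", "geometric"):
        raise ValueError("radius_rule must be 'mean' or 'geometric'")
    if outline.points is not None:
        pts = outline.points
        if np.linalg.matrix_rank(pts - pts.mean(axis=0)) < 2:
            raise ValueError("outline points are collinear; cannot fit an ellipse")
        with np.errstate(divide="ignore", invalid="ignore"):
            # exact circles hit a 0/0 in the orientation angle, which is
            # irrelevant to the circle reduction
            model = EllipseModel.from_estimate(pts)
        if not model:
            raise ValueError("degenerate outline: ellipse fit failed")
        (xc, yc), (a, b) = model.center, model.axis_lengths
        a, b = max(a, b), min(a, b)
        if b <= 0 or not np.all(np.isfinite([xc, yc, a, b])):
            raise ValueError("degenerate outline: ellipse fit failed")
        center = (float(xc), float(yc))
        radius = (a + b) / 2.0 if radius_rule == "mean" else math.sqrt(a * b)
        dist = np.hypot(pts[:, 0] - xc, pts[:, 1] - yc)
        residual = float(np.sqrt(np.mean((dist - radius) ** 2)))
    else:
        center, a, b, _ = outline.ellipse
        center = (float(center[0]), float(center[1]))
        radius = (a + b) / 2.0 if radius_rule == "mean" else math.sqrt(a * b)
        residual = 0.0
    return CircleFit(
        frame_index=outline.frame_index,
        center=center,
        radius=float(radius),
        residual=residual,
    )


def normalize_trajectory(fits: list) -> RingTrajectory:
    """Normalize ordered circle fits to the first timepoint: its centre
    becomes (0, 0) and its radius 1."""
    if len(fits) < 2:
        raise ValueError("need at least 2 circle fits")
    c0 = np.asarray(fits[0].center, dtype=float)
    r0 = fits[0].radius
    if r0 <= 0:
        raise ValueError("first-frame radius must be > 0")
    centers = np.array([f.center for f in fits], dtype=float)
    radii = np.array([f.radius for f in fits], dtype=float)
    return RingTrajectory(
        fits=list(fits),
        normalized_centers=(centers - c0) / r0,
        normalized_radii=radii / r0,
    )


def symmetry_value(trajectory: RingTrajectory) -> float:
    """Distance between the first-timepoint cell centre (the origin after
    normalization) and the last measured ring centre."""
    last = trajectory.normalized_centers[-1]
    return float(np.hypot(last[0], last[1]))


def classify_symmetry(value: float, config: QuantConfig | None = None) -> str:
    """Map a symmetry value to its closure category.

    Below ``symmetric_cutoff`` (default 0.2): symmetric; above
    ``high_asym_cutoff`` (default 0.6): highly asymmetric; otherwise
    (boundaries included) asymmetric.
    """
    config = config or QuantConfig()
    if value < 0:
        raise ValueError("symmetry value must be >= 0")
    if value < config.symmetric_cutoff:
        return "symmetric"
    if value > config.high_asym_cutoff:
        return "highly_asymmetric"
    return "asymmetric"


def summarize_symmetry_classes(results: list) -> pd.DataFrame:
    """Counts and percentages (one decimal) per closure category.

    All three categories appear in the output even when empty.
    """
    if len(results) == 0:
        raise ValueError("no symmetry results to summarize")
    counts = {c: 0 for c in CATEGORIES}
    for r in results:
        if r.category not in counts:
            raise ValueError(f"unknown category {r.category!r}")
        counts[r.category] += 1
    total = len(results)
    return pd.DataFrame(
        {
            "category": list(CATEGORIES),
            "count": [counts[c] for c in CATEGORIES],
            "percent": [round(100.0 * counts[c] / total, 1) for c in CATEGORIES],
        }
    )
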