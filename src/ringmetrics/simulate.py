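"""Synthetic dividing-cell movies with known ground truth.

The phantom is a rounded mitotic cell rendered as a spherical shell
(the cortex) around a dimmer cytosolic interior, sitting on a constant
camera background. From a chosen frame onward a Gaussian band of extra
cortical signal appears at the equator — emulating the equatorial
enrichment of contractile-ring proteins such as anillin — and the furrow
then ingresses at a constant rate, optionally drifting to one side to
produce asymmetric ring closure. Photobleaching is exponential per frame
and shot/read noise is applied last.

Every generative parameter and the per-frame geometry (ring centre and
radius, cortex midline path, furrow line) are recorded as ground truth so
that each downstream estimator can be validated against known values.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np

from .movie import Movie
from .linescan import LinescanProfile
from .symmetry import RingOutline

__all__ = [
    "SimParams",
    "GroundTruth",
    "simulate_division_movie",
    "simulate_ring_trajectory",
    "simulate_chromatin_movie",
    "make_profile_fixture",
    "render_clean_volume",
    "ring_outlines_from_truth",
    "gaussian_band_width",
]


def gaussian_band_width(sigma_um: float, cutoff_fraction: float) -> float:
    """Full width (um) at which a Gaussian band crosses ``cutoff_fraction``
    of its baseline-referenced peak: 2 * sigma * sqrt(2 * ln(1 / cutoff))."""
    if not 0.0 < cutoff_fraction < 1.0:
        raise ValueError("cutoff_fraction must lie in (0, 1)")
    return 2.0 * sigma_um * math.sqrt(2.0 * math.log(1.0 / cutoff_fraction))


@dataclass(frozen=True)
class SimParams:
    """Generative parameters of the synthetic dividing cell.

    Defaults emulate the imaging conditions of the quantified experiments:
    1 um Z steps acquired every minute at high magnification (0.2 um pixels),
    a ~10 um-radius rounded mitotic cell with a ~1 um cortical shell, an
    8-fold equatorial enrichment of 2 um Gaussian breadth appearing shortly
    after anaphase onset, closure in ~16 min, mild bleaching and ~5 %
    Gaussian noise.
    """

    image_shape: tuple[int, int] = (160, 160)
    n_slices: int = 8
    n_frames: int = 20
    pixel_size_um: float = 0.2
    z_step_um: float = 1.0
    frame_interval_min: float = 1.0
    cell_radius_um: float = 10.0
    cortex_thickness_um: float = 1.0
    cytosol_level: float = 120.0
    cortex_level: float = 300.0
    equatorial_enrichment_fold: float = 8.0
    enrichment_sigma_um: float = 2.0
    enrichment_onset_frame: int = 1
    ingression_start_frame: int = 2
    ingression_rate_um_per_min: float = 0.625
    closure_asymmetry: float = 0.0
    bleach_rate_per_frame: float = 0.02
    background_level: float = 50.0
    noise_model: str = "gaussian"  # "none" | "gaussian" | "poisson"
    noise_sigma: float = 15.0  # a.u.; used only by the gaussian model
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "pixel_size_um",
            "z_step_um",
            "frame_interval_min",
            "cell_radius_um",
            "cortex_thickness_um",
            "cytosol_level",
            "cortex_level",
            "enrichment_sigma_um",
            "ingression_rate_um_per_min",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        for name in ("closure_asymmetry", "bleach_rate_per_frame", "background_level", "noise_sigma"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.equatorial_enrichment_fold < 1:
            raise ValueError("equatorial_enrichment_fold must be >= 1")
        if self.closure_asymmetry > 1:
            raise ValueError("closure_asymmetry must lie in [0, 1]")
        if self.noise_model not in ("none", "gaussian", "poisson"):
            raise ValueError("noise_model must be 'none', 'gaussian' or 'poisson'")
        if self.n_frames < 1 or self.n_slices < 1:
            raise ValueError("n_frames and n_slices must be >= 1")
        radius_px = self.cell_radius_um / self.pixel_size_um
        margin_px = self.cortex_thickness_um / self.pixel_size_um + 2
        if 2 * (radius_px + margin_px) > min(self.image_shape):
            raise ValueError(
                "image too small to contain the cell: need at least "
                f"{int(2 * (radius_px + margin_px)) + 1} px per side for a "
                f"{self.cell_radius_um} um cell at {self.pixel_size_um} um/px"
            )

    def to_dict(self) -> dict:
        d = asdict(self)
        d["image_shape"] = list(self.image_shape)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimParams":
        d = dict(d)
        if "image_shape" in d:
            d["image_shape"] = tuple(d["image_shape"])
        return cls(**d)


@dataclass
class GroundTruth:
    """Generative values and per-frame geometry recorded by the simulator.

    ``per_frame_ring_center`` holds (x, z) coordinates of the furrow ring in
    the end-on plane and ``per_frame_ring_radius`` the ring radius, both in
    pixel units. ``cortex_path`` is the (x, y) midline of the cortex in the
    central slice from pole to pole along the side toward which an
    asymmetric ring drifts, one polyline per frame; ``furrow_line`` is a
    short straight segment crossing that path at the equator.
    """

    params: SimParams
    true_breadth_um: float  # full width of the band at the 50 % cutoff
    true_enrichment_fold: float
    true_cortex_cytosol_ratio: float
    true_ingression_duration_min: float | None
    true_symmetry_value: float
    anaphase_frame: int
    closure_frame: int | None
    per_frame_ring_center: np.ndarray  # (T, 2) px, (x, z)
    per_frame_ring_radius: np.ndarray  # (T,) px
    cortex_path: list  # per frame: (N, 2) array of (x, y) px
    furrow_line: list  # per frame: (2, 2) array of (x, y) px

    def __post_init__(self) -> None:
        t = self.params.n_frames
        if not (
            len(self.per_frame_ring_center) == t
            and len(self.per_frame_ring_radius) == t
            and len(self.cortex_path) == t
            and len(self.furrow_line) == t
        ):
            raise ValueError("per-frame ground-truth arrays must have length n_frames")
        r = np.asarray(self.per_frame_ring_radius)[self.params.ingression_start_frame :]
        if np.any(np.diff(r) > 1e-9):
            raise ValueError("ring radii must be non-increasing after ingression start")

    def breadth_at(self, cutoff_fraction: float) -> float:
        """True band width (um) at an arbitrary cutoff fraction."""
        return gaussian_band_width(self.params.enrichment_sigma_um, cutoff_fraction)

    def furrow_width_trace_px(self) -> np.ndarray:
        """Per-frame furrow diameter in pixels (the ingression input trace)."""
        return 2.0 * np.asarray(self.per_frame_ring_radius, dtype=float)


def _frame_geometry(p: SimParams, t: int) -> tuple[float, float]:
    """Furrow (ring) radius and ring-centre x-offset at frame ``t``, in um."""
    r = p.cell_radius_um
    if t >= p.ingression_start_frame:
        dt = (t - p.ingression_start_frame) * p.frame_interval_min
        r = max(p.cell_radius_um - p.ingression_rate_um_per_min * dt, 0.0)
    progress = (p.cell_radius_um - r) / p.cell_radius_um
    offset = p.closure_asymmetry * p.cell_radius_um * progress
    return r, offset


def render_clean_volume(p: SimParams, t: int) -> np.ndarray:
    """Render the noiseless, bleach-free, background-free Z x Y x X volume
    of frame ``t``.

    The cell is a surface of revolution about the pole-to-pole (y) axis:
    a sphere whose radius profile is pinched at the equator as the furrow
    ingresses, with the equatorial cross-section shifted sideways in
    proportion to ``closure_asymmetry``. The cortical shell carries the
    Gaussian enrichment band; the interior carries the cytosolic level.
    """
    ny, nx = p.image_shape
    nz = p.n_slices
    px = p.pixel_size_um
    cy, cx = (ny - 1) / 2.0, (nx - 1) / 2.0
    R = p.cell_radius_um
    half_shell = p.cortex_thickness_um / 2.0

    r_furrow, offset_um = _frame_geometry(p, t)
    pinch_w = p.enrichment_sigma_um  # the band sets where the cortex constricts

    y_um = (np.arange(ny) - cy) * px  # distance from equatorial plane
    pinch = np.exp(-(y_um**2) / (2.0 * pinch_w**2))
    sphere = np.sqrt(np.clip(R**2 - y_um**2, 0.0, None))
    rho = sphere * (1.0 - (1.0 - r_furrow / R) * pinch)  # cross-section radius
    cx_um = offset_um * pinch  # cross-section centre shift

    # Signed distance to the surface of revolution. Near the equator the
    # per-row cross-section distance (r_xz - rho) is normalized by the
    # meridian slope so that the shell has uniform thickness measured
    # along the surface normal; near the poles, where the slope diverges,
    # the exact spherical distance is used instead (the pinch and the
    # asymmetry offset are equator-local and vanish there).
    drho = np.gradient(rho, y_um)
    scale = 1.0 / np.sqrt(1.0 + drho**2)
    near_equator = np.abs(y_um) <= 0.8 * R

    # Enrichment weight along the meridian, by arc length from the equator.
    arc = R * np.arcsin(np.clip(y_um / R, -1.0, 1.0))
    fold = p.equatorial_enrichment_fold if t >= p.enrichment_onset_frame else 1.0
    gain = 1.0 + (fold - 1.0) * np.exp(-(arc**2) / (2.0 * p.enrichment_sigma_um**2))
    cortex_val = p.cortex_level * gain  # per-row cortical intensity

    x_um = (np.arange(nx) - cx) * px
    dx_c = x_um[None, :] - cx_um[:, None]  # offset-corrected, (Y, X)
    dx0 = np.broadcast_to(x_um[None, :], (ny, nx))
    vol = np.zeros((nz, ny, nx), dtype=np.float64)
    for k in range(nz):
        z_um = (k - (nz - 1) / 2.0) * p.z_step_um
        d_eq = (np.sqrt(dx_c**2 + z_um**2) - rho[:, None]) * scale[:, None]
        d_pol = np.sqrt(dx0**2 + y_um[:, None] ** 2 + z_um**2) - R
        dist = np.where(near_equator[:, None], d_eq, d_pol)
        # Partial-volume anti-aliasing: weights ramp linearly over ~2 px
        # at the shell edges (a stand-in for optical blur) instead of
        # switching discontinuously.
        edge = 2.0 * px
        w_shell = np.clip((half_shell - np.abs(dist)) / edge + 0.5, 0.0, 1.0)
        w_inside = np.clip((-dist - half_shell) / edge + 0.5, 0.0, 1.0)
        vol[k] = w_shell * cortex_val[:, None] + w_inside * p.cytosol_level
    return vol


def _truth_cortex_path(p: SimParams, t: int, n_theta: int = 181) -> np.ndarray:
    """Cortex midline (x, y) in the central slice, pole to pole on the +x side."""
    ny, nx = p.image_shape
    px = p.pixel_size_um
    cy, cx = (ny - 1) / 2.0, (nx - 1) / 2.0
    R = p.cell_radius_um
    r_furrow, offset_um = _frame_geometry(p, t)
    pinch_w = p.enrichment_sigma_um

    theta = np.linspace(-0.97 * np.pi / 2, 0.97 * np.pi / 2, n_theta)
    y_um = R * np.sin(theta)
    pinch = np.exp(-(y_um**2) / (2.0 * pinch_w**2))
    rho = R * np.cos(theta) * (1.0 - (1.0 - r_furrow / R) * pinch)
    x_px = cx + (offset_um * pinch + rho) / px
    y_px = cy + y_um / px
    return np.column_stack([x_px, y_px])


def _truth_furrow_line(p: SimParams, t: int, half_len_px: float = 8.0) -> np.ndarray:
    ny, nx = p.image_shape
    px = p.pixel_size_um
    cy, cx = (ny - 1) / 2.0, (nx - 1) / 2.0
    r_furrow, offset_um = _frame_geometry(p, t)
    x_eq = cx + (offset_um + r_furrow) / px
    return np.array([[x_eq - half_len_px, cy], [x_eq + half_len_px, cy]])


def simulate_division_movie(params: SimParams) -> tuple[Movie, GroundTruth]:
    """Generate a dividing-cell movie and its ground truth.

    Per frame the clean volume is rendered, multiplied by the bleach factor
    ``(1 - bleach_rate) ** t``, offset by the constant background, and then
    noised (Gaussian of fixed sigma, or Poisson treating the a.u. value as
    the expected count). Identical parameters — including the seed — yield
    bit-identical output.
    """
    p = params
    rng = np.random.default_rng(p.seed)
    frames = []
    centers = np.zeros((p.n_frames, 2))
    radii = np.zeros(p.n_frames)
    paths, furrows = [], []
    ny, nx = p.image_shape
    cy, cx = (ny - 1) / 2.0, (nx - 1) / 2.0

    for t in range(p.n_frames):
        vol = render_clean_volume(p, t)
        vol *= (1.0 - p.bleach_rate_per_frame) ** t
        vol += p.background_level
        if p.noise_model == "gaussian":
            vol = vol + rng.normal(0.0, p.noise_sigma, size=vol.shape)
            vol = np.clip(vol, 0.0, None)
        elif p.noise_model == "poisson":
            vol = rng.poisson(np.clip(vol, 0.0, None)).astype(np.float64)
        frames.append(vol)

        r_um, off_um = _frame_geometry(p, t)
        centers[t] = (cx + off_um / p.pixel_size_um, 0.0)  # end-on (x, z) px
        radii[t] = r_um / p.pixel_size_um
        paths.append(_truth_cortex_path(p, t))
        furrows.append(_truth_furrow_line(p, t))

    data = np.stack(frames)
    movie = Movie(
        data=data,
        pixel_size_um=p.pixel_size_um,
        z_step_um=p.z_step_um,
        frame_interval_min=p.frame_interval_min,
        channel_name="ring",
    )

    closure_frame = None
    width_px = 2.0 * radii
    for t in range(p.ingression_start_frame, p.n_frames):
        if width_px[t] <= 1.0:
            closure_frame = t
            break
    duration = (
        (closure_frame - p.ingression_start_frame) * p.frame_interval_min
        if closure_frame is not None
        else None
    )

    truth = GroundTruth(
        params=p,
        true_breadth_um=gaussian_band_width(p.enrichment_sigma_um, 0.5),
        true_enrichment_fold=p.equatorial_enrichment_fold,
        true_cortex_cytosol_ratio=p.cortex_level / p.cytosol_level,
        true_ingression_duration_min=duration,
        true_symmetry_value=p.closure_asymmetry,
        anaphase_frame=p.ingression_start_frame,
        closure_frame=closure_frame,
        per_frame_ring_center=centers,
        per_frame_ring_radius=radii,
        cortex_path=paths,
        furrow_line=furrows,
    )
    return movie, truth


def simulate_chromatin_movie(params: SimParams) -> Movie:
    """Chromatin channel for visual QC only: two Gaussian blobs separating
    along the pole-to-pole axis as the frames advance. Never quantified."""
    p = params
    ny, nx = p.image_shape
    nz = p.n_slices
    cy, cx = (ny - 1) / 2.0, (nx - 1) / 2.0
    px = p.pixel_size_um
    sigma_px = 1.5 / px
    yy, xx = np.mgrid[0:ny, 0:nx]
    frames = []
    for t in range(p.n_frames):
        sep_um = min(0.6 * p.cell_radius_um, 0.08 * p.cell_radius_um * t)
        img = np.zeros((ny, nx))
        for sign in (-1.0, 1.0):
            by = cy + sign * sep_um / px
            img += 200.0 * np.exp(-(((yy - by) ** 2 + (xx - cx) ** 2) / (2 * sigma_px**2)))
        frames.append(np.repeat(img[None, :, :], nz, axis=0))
    return Movie(
        data=np.stack(frames),
        pixel_size_um=p.pixel_size_um,
        z_step_um=p.z_step_um,
        frame_interval_min=p.frame_interval_min,
        channel_name="chromatin",
    )


def simulate_ring_trajectory(
    n_frames: int,
    initial_radius: float,
    asymmetry: float,
    seed: int = 0,
    jitter: float = 0.0,
    initial_center: tuple[float, float] = (0.0, 0.0),
) -> list[tuple[tuple[float, float], float]]:
    """Per-frame (center, radius) of a closing ring, as a lightweight fixture.

    The radius shrinks linearly to ~0 (a 1e-3 floor keeps fits valid) while
    the centre drifts along +x so that the final offset from the initial
    centre equals ``asymmetry * initial_radius``; centre jitter (std in px)
    is added from frame 1 on. Deterministic given the seed.
    """
    if n_frames < 2:
        raise ValueError("n_frames must be >= 2")
    if initial_radius <= 0:
        raise ValueError("initial_radius must be > 0")
    if not 0.0 <= asymmetry <= 1.0:
        raise ValueError("asymmetry must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    c0 = np.asarray(initial_center, dtype=float)
    out = []
    for t in range(n_frames):
        f = t / (n_frames - 1)
        radius = initial_radius * (1.0 - (1.0 - 1e-3) * f)
        center = c0 + np.array([asymmetry * initial_radius * f, 0.0])
        if jitter > 0 and t > 0:
            center = center + rng.normal(0.0, jitter, size=2)
        out.append(((float(center[0]), float(center[1])), float(radius)))
    return out


def ring_outlines_from_truth(
    truth: GroundTruth,
    n_points: int = 12,
    noise_px: float = 0.5,
    seed: int = 0,
    min_radius_px: float = 2.0,
) -> dict[int, RingOutline]:
    """Point outlines of the ring per frame, emulating manual annotation.

    Points are placed on the true end-on ring circle with Gaussian
    positional noise; frames whose ring is smaller than ``min_radius_px``
    are skipped (too small to outline, as for a nearly closed ring).
    """
    rng = np.random.default_rng(seed)
    angles = np.linspace(0, 2 * np.pi, n_points, endpoint=False)
    outlines: dict[int, RingOutline] = {}
    for t in range(truth.params.n_frames):
        r = truth.per_frame_ring_radius[t]
        if r < min_radius_px:
            continue
        cxz = truth.per_frame_ring_center[t]
        pts = np.column_stack(
            [cxz[0] + r * np.cos(angles), cxz[1] + r * np.sin(angles)]
        )
        if noise_px > 0:
            pts = pts + rng.normal(0.0, noise_px, size=pts.shape)
        outlines[t] = RingOutline(frame_index=t, points=pts)
    return outlines


def make_profile_fixture(
    length: int,
    baseline: float,
    peak_height: float,
    peak_center: int,
    peak_sigma: float,
    extra_spikes: list[tuple[int, float]] | None = None,
    pixel_size_um: float = 1.0,
    pole_window_px: int = 50,
) -> LinescanProfile:
    """A 1-D linescan fixture: baseline + Gaussian bump + optional isolated
    spikes (each spike sets the sample at its index to the given value)."""
    if length <= 100:
        raise ValueError("length must exceed 100 so that 50-px pole windows exist")
    if not 0 <= peak_center < length:
        raise ValueError("peak_center must lie within the profile")
    if peak_center < pole_window_px or peak_center >= length - pole_window_px:
        warnings.warn(
            "peak_center lies within a pole window; baseline will overlap the peak",
            stacklevel=2,
        )
    idx = np.arange(length, dtype=float)
    intensity = baseline + peak_height * np.exp(
        -((idx - peak_center) ** 2) / (2.0 * peak_sigma**2)
    )
    for spike_idx, value in extra_spikes or []:
        if not 0 <= spike_idx < length:
            raise ValueError(f"spike index {spike_idx} out of bounds")
        intensity[spike_idx] = value
    return LinescanProfile(
        arc_position_px=idx,
        intensity=intensity,
        furrow_offset_px=idx - peak_center,
        pixel_size_um=pixel_size_um,
        pole_window_px=pole_window_px,
    )
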