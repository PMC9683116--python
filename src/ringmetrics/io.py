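"""File I/O: calibrated multi-page TIFF movies, JSON/CSV annotations,
ground-truth JSON, and provenance-stamped CSV tables."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from ._version import __version__
from .config import QuantConfig
from .linescan import CortexPath, FurrowLine
from .movie import Movie
from .simulate import GroundTruth, SimParams
from .symmetry import RingOutline

__all__ = [
    "read_movie",
    "write_movie",
    "read_annotations",
    "write_annotations",
    "read_truth",
    "write_truth",
    "write_table",
    "read_table",
]


def write_movie(movie: Movie, path) -> None:
    """Write a movie as multi-page TIFF with the TZYX axis order and the
    physical calibration recorded in the shaped metadata."""
    tifffile.imwrite(
        path,
        movie.data.astype(np.float32),
        metadata={
            "axes": "TZYX",
            "pixel_size_um": movie.pixel_size_um,
            "z_step_um": movie.z_step_um,
            "frame_interval_min": movie.frame_interval_min,
            "channel_name": movie.channel_name,
        },
    )


def read_movie(
    path,
    axis_order: str = "TZYX",
    pixel_size_um: float | None = None,
    z_step_um: float | None = None,
    frame_interval_min: float | None = None,
    channel_name: str | None = None,
) -> Movie:
    """Read a multi-page TIFF movie, validating the declared axis order.

    Calibration is taken from the TIFF metadata when present; explicit
    arguments override it. There are no silent physical-unit defaults: a
    movie without calibrated pixel size, Z step and frame interval is
    rejected.
    """
    if axis_order not in ("TZYX", "ZTYX"):
        raise ValueError("axis_order must be 'TZYX' or 'ZTYX'")
    with tifffile.TiffFile(path) as tif:
        data = tif.asarray()
        meta = {}
        if tif.shaped_metadata:
            meta = dict(tif.shaped_metadata[0])
    if data.ndim == 3:  # single-slice movies may drop the Z axis on disk
        data = data[:, None, :, :]
    if data.ndim != 4:
        raise ValueError(
            f"expected a 4-D {axis_order} stack; file has shape {data.shape}"
        )
    declared = meta.get("axes")
    if declared and declared != axis_order and {declared, axis_order} != {"TZYX"}:
        raise ValueError(
            f"axis-order mismatch: file metadata says {declared!r}, caller "
            f"declared {axis_order!r}"
        )
    if axis_order == "ZTYX":
        data = np.swapaxes(data, 0, 1)

    def _calib(arg, key, name):
        value = arg if arg is not None else meta.get(key)
        if value is None or value <= 0:
            raise ValueError(
                f"{name} missing: supply it explicitly or store it in the TIFF metadata"
            )
        return float(value)

    return Movie(
        data=data.astype(np.float64),
        pixel_size_um=_calib(pixel_size_um, "pixel_size_um", "pixel size"),
        z_step_um=_calib(z_step_um, "z_step_um", "z step"),
        frame_interval_min=_calib(frame_interval_min, "frame_interval_min", "frame interval"),
        channel_name=channel_name if channel_name is not None else meta.get("channel_name", ""),
    )


def _coords_from_json(obj, path, frame_key):
    arr = np.asarray(obj, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError(f"{path}: frame {frame_key}: expected rows of (x, y)")
    return arr


def _frames_from_file(path) -> dict[int, np.ndarray]:
    """Read a keyed multi-frame coordinate file (JSON mapping frame ->
    [(x, y), ...], or CSV with frame, x, y columns)."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        with open(path) as fh:
            raw = json.load(fh)
        if isinstance(raw, list):  # single-frame file
            return {0: _coords_from_json(raw, path, 0)}
        return {int(k): _coords_from_json(v, path, k) for k, v in raw.items()}
    frames: dict[int, list] = {}
    with open(path) as fh:
        header = fh.readline().strip().lower().split(",")
        if header != ["frame", "x", "y"]:
            raise ValueError(f"{path}: expected header 'frame,x,y', got {header}")
        for lineno, line in enumerate(fh, start=2):
            line = line.strip()
            if not line:
                continue
            parts = line.split(",")
            if len(parts) != 3:
                raise ValueError(f"{path}: line {lineno}: expected 3 fields")
            try:
                frame, x, y = int(parts[0]), float(parts[1]), float(parts[2])
            except ValueError as exc:
                raise ValueError(f"{path}: line {lineno}: non-numeric value") from exc
            frames.setdefault(frame, []).append((x, y))
    return {k: np.asarray(v, dtype=float) for k, v in frames.items()}


def read_annotations(path, kind: str, width_px: int = 5):
    """Read typed annotations keyed by frame.

    ``kind`` is one of ``cortex_path`` (returns CortexPath per frame),
    ``furrow_line`` (FurrowLine per frame, exactly two points) or
    ``ring_outline`` (RingOutline per frame, >= 5 points).
    """
    frames = _frames_from_file(path)
    if kind == "cortex_path":
        return {
            t: CortexPath(vertices=pts, width_px=width_px, frame_index=t)
            for t, pts in frames.items()
        }
    if kind == "furrow_line":
        out = {}
        for t, pts in frames.items():
            if pts.shape != (2, 2):
                raise ValueError(f"{path}: frame {t}: a furrow line needs exactly 2 points")
            out[t] = FurrowLine(endpoints=pts, frame_index=t)
        return out
    if kind == "ring_outline":
        return {t: RingOutline(frame_index=t, points=pts) for t, pts in frames.items()}
    raise ValueError(f"unknown annotation kind {kind!r}")


def write_annotations(frames: dict, path) -> None:
    """Write frame-keyed coordinate annotations as JSON."""
    payload = {}
    for t, obj in frames.items():
        if isinstance(obj, CortexPath):
            pts = obj.vertices
        elif isinstance(obj, FurrowLine):
            pts = obj.endpoints
        elif isinstance(obj, RingOutline):
            pts = obj.points
        else:
            pts = np.asarray(obj, dtype=float)
        payload[str(int(t))] = np.asarray(pts, dtype=float).tolist()
    with open(path, "w") as fh:
        json.dump(payload, fh)


def write_truth(truth: GroundTruth, path) -> None:
    payload = {
        "params": truth.params.to_dict(),
        "true_breadth_um": truth.true_breadth_um,
        "true_enrichment_fold": truth.true_enrichment_fold,
        "true_cortex_cytosol_ratio": truth.true_cortex_cytosol_ratio,
        "true_ingression_duration_min": truth.true_ingression_duration_min,
        "true_symmetry_value": truth.true_symmetry_value,
        "anaphase_frame": truth.anaphase_frame,
        "closure_frame": truth.closure_frame,
        "per_frame_ring_center": np.asarray(truth.per_frame_ring_center).tolist(),
        "per_frame_ring_radius": np.asarray(truth.per_frame_ring_radius).tolist(),
        "cortex_path": [np.asarray(p).tolist() for p in truth.cortex_path],
        "furrow_line": [np.asarray(f).tolist() for f in truth.furrow_line],
    }
    with open(path, "w") as fh:
        json.dump(payload, fh)


def read_truth(path) -> GroundTruth:
    with open(path) as fh:
        payload = json.load(fh)
    return GroundTruth(
        params=SimParams.from_dict(payload["params"]),
        true_breadth_um=payload["true_breadth_um"],
        true_enrichment_fold=payload["true_enrichment_fold"],
        true_cortex_cytosol_ratio=payload["true_cortex_cytosol_ratio"],
        true_ingression_duration_min=payload["true_ingression_duration_min"],
        true_symmetry_value=payload["true_symmetry_value"],
        anaphase_frame=payload["anaphase_frame"],
        closure_frame=payload["closure_frame"],
        per_frame_ring_center=np.asarray(payload["per_frame_ring_center"]),
        per_frame_ring_radius=np.asarray(payload["per_frame_ring_radius"]),
        cortex_path=[np.asarray(p) for p in payload["cortex_path"]],
        furrow_line=[np.asarray(f) for f in payload["furrow_line"]],
    )


def write_table(df: pd.DataFrame, path, config: QuantConfig | None = None) -> None:
    """Write a tidy CSV with provenance header comments (software version,
    configuration hash and thresholds)."""
    with open(path, "w") as fh:
        fh.write(f"# ringmetrics {__version__}\n")
        if config is not None:
            fh.write(f"# config_hash {config.hash()}\n")
            fh.write(f"# config {json.dumps(config.to_dict(), sort_keys=True)}\n")
        df.to_csv(fh, index=False)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")
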