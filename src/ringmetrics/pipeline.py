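"""End-to-end orchestration of the three analyses: linescan metrics over
time, per-cell summary statistics, and ring-closure symmetry."""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as rio
from .config import QuantConfig
from .linescan import extract_cortical_linescan, normalize_profile, register_to_furrow
from .metrics import furrow_enrichment, ingression_duration, peak_breadth
from .preprocess import preprocess_movie
from .symmetry import (
    classify_symmetry,
    fit_circle,
    normalize_trajectory,
    summarize_symmetry_classes,
    symmetry_value,
    SymmetryResult,
)

logger = logging.getLogger("ringmetrics")

__all__ = ["AnalysisManifest", "run_pipeline"]


@dataclass
class AnalysisManifest:
    """Inputs, calibration overrides and configuration for one cell.

    Annotation paths left as ``None`` cause the corresponding analysis to
    be skipped (with a logged reason) rather than aborting the run.
    """

    movie_path: str
    out_dir: str
    cell_id: str = "cell"
    cell_line: str = ""
    axis_order: str = "TZYX"
    cortex_paths: str | None = None
    furrow_lines: str | None = None
    ring_outlines: str | None = None
    furrow_width_trace: str | None = None  # JSON list of per-frame widths (px)
    anaphase_frame: int | None = None
    pixel_size_um: float | None = None
    z_step_um: float | None = None
    frame_interval_min: float | None = None
    n_central_slices: int = 2
    background_method: str = "percentile"
    background_roi: tuple[int, int, int, int] | None = None
    bleach_method: str = "simple_ratio"
    config: QuantConfig = field(default_factory=QuantConfig)
    seed: int = 0

    @classmethod
    def from_json(cls, path) -> "AnalysisManifest":
        base = Path(path).parent
        with open(path) as fh:
            raw = json.load(fh)
        if "config" in raw:
            raw["config"] = QuantConfig.from_dict(raw["config"])
        for key in ("movie_path", "cortex_paths", "furrow_lines", "ring_outlines",
                    "furrow_width_trace", "out_dir"):
            if raw.get(key):
                p = Path(raw[key])
                raw[key] = str(p if p.is_absolute() else base / p)
        return cls(**raw)


def _linescan_stage(plane, paths, furrows, manifest, config):
    rows = []
    profile_rows = []
    for t in sorted(paths):
        path = paths[t]
        try:
            profile = extract_cortical_linescan(
                plane, path, pole_window_px=config.pole_window_px
            )
            if furrows is not None and t in furrows:
                profile = register_to_furrow(profile, furrows[t])
            profile = normalize_profile(profile, baseline_mode=config.baseline_mode)
            breadth = peak_breadth(profile, config)
            enrich = furrow_enrichment(profile, breadth, config)
            rows.append(
                {
                    "cell_id": manifest.cell_id,
                    "cell_line": manifest.cell_line,
                    "frame": t,
                    "breadth_px": breadth.breadth_px,
                    "breadth_um": breadth.breadth_um,
                    "breadth_fraction": breadth.breadth_fraction,
                    "excluded_pixel_count": breadth.excluded_pixel_count,
                    "furrow_mean": enrich.furrow_mean,
                    "pole_mean": enrich.pole_mean,
                    "enrichment_ratio": enrich.enrichment_ratio,
                    "error": "",
                }
            )
            offsets = (
                profile.furrow_offset_px
                if profile.furrow_offset_px is not None
                else np.full(len(profile), np.nan)
            )
            for arc, off, inten in zip(profile.arc_position_px, offsets, profile.intensity):
                profile_rows.append(
                    {"frame": t, "arc_position_px": arc, "furrow_offset_px": off,
                     "intensity": inten}
                )
        except ValueError as exc:
            logger.warning("linescan failed for frame %d: %s", t, exc)
            rows.append(
                {"cell_id": manifest.cell_id, "cell_line": manifest.cell_line,
                 "frame": t, "error": str(exc)}
            )
    return pd.DataFrame(rows), pd.DataFrame(profile_rows)


def _symmetry_stage(outlines, manifest, config):
    fits = [
        fit_circle(outlines[t], radius_rule=config.circle_radius_rule)
        for t in sorted(outlines)
    ]
    trajectory = normalize_trajectory(fits)
    value = symmetry_value(trajectory)
    category = classify_symmetry(value, config)
    traj_df = pd.DataFrame(
        {
            "frame": [f.frame_index for f in fits],
            "center_x_px": [f.center[0] for f in fits],
            "center_y_px": [f.center[1] for f in fits],
            "radius_px": [f.radius for f in fits],
            "residual_px": [f.residual for f in fits],
            "norm_center_x": trajectory.normalized_centers[:, 0],
            "norm_center_y": trajectory.normalized_centers[:, 1],
            "norm_radius": trajectory.normalized_radii,
        }
    )
    sym_df = pd.DataFrame(
        [{"cell_id": manifest.cell_id, "cell_line": manifest.cell_line,
          "symmetry_value": value, "category": category}]
    )
    return traj_df, sym_df, SymmetryResult(symmetry_value=value, category=category)


def run_pipeline(manifest: AnalysisManifest) -> dict:
    """Run every analysis the manifest provides annotations for.

    Outputs are deterministic given identical inputs and seed; every CSV
    carries the configuration hash. Missing annotations skip the affected
    stage with a logged reason; per-frame failures are recorded per row
    without aborting the batch. Returns the result tables keyed by name.
    """
    config = manifest.config
    out_dir = Path(manifest.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    results: dict[str, pd.DataFrame] = {}

    movie = rio.read_movie(
        manifest.movie_path,
        axis_order=manifest.axis_order,
        pixel_size_um=manifest.pixel_size_um,
        z_step_um=manifest.z_step_um,
        frame_interval_min=manifest.frame_interval_min,
    )
    background_kwargs = {}
    if manifest.background_method == "roi":
        roi = manifest.background_roi or (0, 24, 0, 24)
        background_kwargs["roi"] = tuple(roi)
    _, plane = preprocess_movie(
        movie,
        n_central_slices=manifest.n_central_slices,
        background_method=manifest.background_method,
        bleach_method=manifest.bleach_method,
        **background_kwargs,
    )

    if manifest.cortex_paths:
        paths = rio.read_annotations(
            manifest.cortex_paths, "cortex_path", width_px=config.linescan_width_px
        )
        furrows = (
            rio.read_annotations(manifest.furrow_lines, "furrow_line")
            if manifest.furrow_lines
            else None
        )
        metrics_df, profiles_df = _linescan_stage(plane, paths, furrows, manifest, config)
        rio.write_table(metrics_df, out_dir / "linescan_metrics.csv", config)
        rio.write_table(profiles_df, out_dir / "profiles.csv", config)
        results["linescan_metrics"] = metrics_df
        results["profiles"] = profiles_df
    else:
        logger.info("no cortex paths supplied; linescan stage skipped")

    if manifest.furrow_width_trace and manifest.anaphase_frame is not None:
        with open(manifest.furrow_width_trace) as fh:
            trace = np.asarray(json.load(fh), dtype=float)
        result = ingression_duration(
            trace, manifest.anaphase_frame, movie.frame_interval_min, config
        )
        ingress_df = pd.DataFrame(
            [{"cell_id": manifest.cell_id, "cell_line": manifest.cell_line,
              "closed": result.closed, "closure_frame": result.closure_frame,
              "duration_min": result.duration_min}]
        )
        rio.write_table(ingress_df, out_dir / "ingression.csv", config)
        results["ingression"] = ingress_df
    else:
        logger.info("no furrow width trace / anaphase frame; ingression stage skipped")

    if manifest.ring_outlines:
        outlines = rio.read_annotations(manifest.ring_outlines, "ring_outline")
        traj_df, sym_df, sym = _symmetry_stage(outlines, manifest, config)
        rio.write_table(traj_df, out_dir / "ring_trajectory.csv", config)
        rio.write_table(sym_df, out_dir / "symmetry.csv", config)
        results["ring_trajectory"] = traj_df
        results["symmetry"] = sym_df
        results["symmetry_summary"] = summarize_symmetry_classes([sym])
    else:
        logger.info("no ring outlines supplied; symmetry stage skipped")

    return results
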