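"""Config-driven orchestration: run analyses over movie lists, write CSVs.

A :class:`StudyConfig` (usually read from YAML) lists input movies with
their calibration and group labels, selects an analysis, and names an
output directory.  :func:`run_pipeline` executes the analysis per file,
writes per-cell CSV rows, a per-group summary with the requested
statistical comparison, and a run manifest recording every parameter
(defaults included) so any number in the outputs can be reproduced.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import dynamics, fluorescence, organization, profiles, stats, tracking
from .movie import Movie

log = logging.getLogger("tipkit")

ANALYSES = ("growth", "tipcv", "pmcs", "actin_dynamics", "filaments", "profile")


@dataclass
class InputFile:
    path: str
    pixel_size: float
    frame_interval: float
    group: str = "default"
    channel_label: str = ""


@dataclass
class StudyConfig:
    inputs: list[InputFile]
    analysis: str
    out_dir: str
    params: dict = field(default_factory=dict)
    comparison: str | None = None        # "t", "anova_tukey", "ranksum"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.analysis not in ANALYSES:
            raise ValueError(f"unknown analysis {self.analysis!r}; choose from {ANALYSES}")
        if not self.inputs:
            raise ValueError("empty input file list")
        missing = [f.path for f in self.inputs if not Path(f.path).exists()]
        if missing:
            raise FileNotFoundError(f"missing inputs: {missing}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "StudyConfig":
        raw = yaml.safe_load(Path(path).read_text())
        inputs = [InputFile(**f) for f in raw.pop("inputs")]
        return cls(inputs=inputs, **raw)


def _analyze_one(movie: Movie, analysis: str, params: dict) -> dict:
    """One scalar row per cell, per analysis kind."""
    if analysis == "growth":
        track = tracking.track_tip(movie)
        gs = tracking.growth_series(track, params.get("rate_interval_s"))
        return {
            "mean_rate_um_per_min": gs.mean_rate,
            "mean_rate_growing": gs.mean_rate_growing,
            "max_rate_um_per_min": gs.max_rate,
            "cessation_time_s": gs.cessation_time_s,
            "_value": gs.mean_rate,
        }
    if analysis == "tipcv":
        track = tracking.track_tip(movie)
        cv = fluorescence.tip_cv(movie, track, radius_um=params.get("roi_radius_um", 2.0))
        return {"tip_cv": cv, "roi_radius_um": params.get("roi_radius_um", 2.0), "_value": cv}
    if analysis == "pmcs":
        track = tracking.track_tip(movie)
        rois = tracking.pm_cs_rois(
            track, movie, cs_offset_um=params.get("cs_offset_um", 0.5)
        )
        series = fluorescence.pm_cs_ratio(movie, rois)
        return {"mean_pm_cs_ratio": series.mean_ratio, "_value": series.mean_ratio}
    if analysis == "actin_dynamics":
        activity, _ = dynamics.analyze_cell(
            movie,
            size_um=params.get("tile_um", 6.0),
            offset_um=params.get("offset_um", 3.0),
            top_n=params.get("top_n", 10),
        )
        return {
            "mean_k_per_s": activity.mean_k,
            "n_converged": sum(f.converged for f in activity.fits),
            "_value": activity.mean_k,
        }
    if analysis == "filaments":
        fs = organization.detect_filaments(
            movie.frames[0],
            pixel_size=movie.pixel_size,
            min_len_um=params.get("min_len_um", 1.0),
        )
        mean_len = float(fs.lengths_um.mean()) if len(fs) else np.nan
        return {"n_segments": len(fs), "mean_length_um": mean_len, "_value": mean_len}
    if analysis == "profile":
        track = tracking.track_tip(movie)
        prof = profiles.axial_profile(movie, track, params.get("max_dist_um", 12.0))
        peak, tie = profiles.peak_distance(prof)
        return {"peak_distance_um": peak, "peak_tie": tie, "_value": peak}
    raise AssertionError(analysis)


def run_pipeline(config: StudyConfig) -> pd.DataFrame:
    """Execute the configured analysis on every input; returns per-cell rows.

    Per-file failures are logged and skipped; if every file fails, an
    error is raised.  Writes ``cells.csv``, ``groups.csv`` (with the
    statistical comparison when configured) and ``manifest.json`` into the
    output directory.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for f in config.inputs:
        try:
            movie = Movie.load(f.path, f.pixel_size, f.frame_interval, f.channel_label)
            res = _analyze_one(movie, config.analysis, config.params)
        except Exception as exc:          # noqa: BLE001 — per-file isolation
            log.warning("skipping %s: %s", f.path, exc)
            continue
        rows.append({"file": f.path, "group": f.group, **res})
    if not rows:
        raise RuntimeError("all input files failed")
    cells = pd.DataFrame(rows)
    cells.drop(columns="_value").to_csv(out / "cells.csv", index=False, float_format="%.6g")

    groups = cells.groupby("group")["_value"]
    summary = groups.agg(["count", "mean", "std"]).reset_index()
    comparison = None
    if config.comparison and cells["group"].nunique() >= 2:
        by_group = {g: v.to_numpy() for g, v in groups}
        comparison = stats.compare_groups(by_group, config.comparison)
        summary["test"] = comparison.test
        summary["statistic"] = comparison.statistic
        summary["p_value"] = comparison.p_value
    summary.to_csv(out / "groups.csv", index=False, float_format="%.6g")

    manifest = {
        "analysis": config.analysis,
        "seed": config.seed,
        "params": config.params,
        "comparison": config.comparison,
        "inputs": [dataclasses.asdict(f) for f in config.inputs],
        "defaults": {
            "tracking": {"entry_border": "left", "std_radius": 3, "close_radius": 10,
                         "jump_limit_um": 2.0},
            "tipcv": {"roi_radius_um": config.params.get("roi_radius_um", 2.0)},
            "pmcs": {"cs_offset_um": config.params.get("cs_offset_um", 0.5),
                     "ring_width_um": 0.4},
            "actin_dynamics": {"tile_um": 6.0, "offset_um": 3.0, "top_n": 10},
            "filaments": {"min_len_um": 1.0, "line_len_px": 7, "smooth_sigma": 1.5},
            "profile": {"max_dist_um": config.params.get("max_dist_um", 12.0)},
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, default=str))
    return cells
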