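"""End-to-end session analysis: preprocess -> kinematics -> latency -> stats.

``analyze_session`` is the in-memory workhorse; ``run_session_analysis``
wraps it with disk I/O, per-animal overrides, logging and provenance
(package version + config hash) for the command-line entry point.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from . import __version__
from .kinematics import (
    DEFAULT_ROLLING_WINDOW,
    DEFAULT_WINSOR_CAP,
    rolling_velocity,
    vertical_velocity,
    winsorized_mean_velocity,
)
from .learning import (
    DEFAULT_BURST_FRACTION,
    DEFAULT_SURFACE_RADIUS,
    T1Result,
    distance_to_site,
    first_surface_bound_time,
    locate_food_drop,
    session_summary,
    surface_arrivals,
    trial_success,
    velocity_bursts,
)
from .preprocess import PreprocessConfig, preprocess_pipeline
from .stats import wilcoxon_signed_rank
from .trackio import SessionTable, TrialMeta, load_session

__all__ = ["RunConfig", "analyze_session", "run_session_analysis"]


@dataclass
class RunConfig:
    """Configuration of a full analysis run.

    ``overrides`` maps fish_id to per-animal ``burst_fraction`` /
    ``surface_radius`` replacements (the logged equivalent of hand-tuning
    individual animals); unknown keys in a config mapping are rejected.
    """

    track_dir: str = ""
    meta_path: str = ""
    out_dir: str = "results"
    fps: float = 20.0
    likelihood_threshold: float = 0.999
    jump_quantile: float = 0.05
    keypoints: tuple[str, ...] = ("head",)
    rolling_window: int = DEFAULT_ROLLING_WINDOW
    winsor_cap: float = DEFAULT_WINSOR_CAP
    burst_fraction: float = DEFAULT_BURST_FRACTION
    surface_radius: float = DEFAULT_SURFACE_RADIUS
    learning_k: int = 2
    seed: int = 0
    overrides: dict = field(default_factory=dict)

    @classmethod
    def from_mapping(cls, mapping: Mapping) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(mapping) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = dict(mapping)
        if "keypoints" in cfg:
            cfg["keypoints"] = tuple(cfg["keypoints"])
        return cls(**cfg)

    def hash(self) -> str:
        """Hash of the analysis inputs and parameters (not the output path)."""
        payload = dataclasses.asdict(self)
        payload.pop("out_dir")
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()[:12]


def analyze_session(
    session: SessionTable, config: RunConfig | None = None
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Run the automated latency pipeline on a loaded session.

    Returns (per-trial results, per-fish summaries, per-track filter
    reports). Per-trial columns include the thresholds actually used so
    per-animal overrides stay auditable.
    """
    cfg = config or RunConfig()
    pre_cfg = PreprocessConfig(
        likelihood_threshold=cfg.likelihood_threshold,
        jump_quantile=cfg.jump_quantile,
        keypoints=tuple(cfg.keypoints),
    )
    clean, reports = preprocess_pipeline(session, pre_cfg)

    rows: list[dict] = []
    summaries: list[dict] = []
    for fish_id in clean.fish_ids():
        tracks = clean.trials_of(fish_id)
        metas = clean.meta_of(fish_id)
        ov = cfg.overrides.get(fish_id, {})
        fraction = float(ov.get("burst_fraction", cfg.burst_fraction))
        radius = float(ov.get("surface_radius", cfg.surface_radius))

        site = locate_food_drop(tracks)
        kin = {}
        for trial, track in tracks.items():
            k = rolling_velocity(vertical_velocity(track), window=cfg.rolling_window)
            k.dist_food = distance_to_site(track, site)
            kin[trial] = k
        bursts, threshold = velocity_bursts(kin, fraction=fraction)

        results: dict[int, T1Result] = {}
        for trial, track in tracks.items():
            meta = metas.get(trial, TrialMeta(fish_id=fish_id, trial_number=trial))
            dist = kin[trial].dist_food
            valid = dist.notna().to_numpy()
            if not valid.any():
                continue  # trial unusable: no defined position at all
            first_valid = int(np.argmax(valid))
            at_start = bool(dist.iloc[first_valid] <= radius)
            arrivals = surface_arrivals(dist.dropna(), radius=radius, fps=track.fps)
            t1 = first_surface_bound_time(bursts[trial], arrivals, meta, at_start)
            res = T1Result(
                fish_id=fish_id, trial_number=trial, t1=t1,
                success=trial_success(t1, meta), method="auto",
                burst_threshold_used=threshold, surface_threshold_used=radius,
            )
            results[trial] = res
            rows.append(dataclasses.asdict(res))

        wv = winsorized_mean_velocity(kin, cap=cfg.winsor_cap)
        summ = session_summary(fish_id, results, metas, winsorized_velocity=wv)
        summaries.append(dataclasses.asdict(summ))

    t1_df = pd.DataFrame(rows)
    summary_df = pd.DataFrame(summaries).drop(columns=["extras"], errors="ignore")
    return t1_df, summary_df, reports


def run_session_analysis(config: RunConfig) -> dict:
    """Disk-to-disk run: load, analyze, test early vs late, write the bundle.

    Outputs per-trial and per-fish CSVs, a group-comparison JSON (paired
    signed-rank of early vs late mean t1 and percent success over included
    fish) and a provenance log. Deterministic given config and seed.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    session = load_session(config.track_dir, config.meta_path, fps=config.fps)
    t1_df, summary_df, reports = analyze_session(session, config)

    header = f"# killicog {__version__} config={config.hash()}\n"
    t1_path = out_dir / "t1_results.csv"
    with open(t1_path, "w") as fh:
        fh.write(header)
        t1_df.to_csv(fh, index=False)
    summary_path = out_dir / "session_summary.csv"
    with open(summary_path, "w") as fh:
        fh.write(header)
        summary_df.to_csv(fh, index=False)

    stats_out: dict = {"n_fish": int(len(summary_df))}
    included = summary_df[summary_df["included"]]
    if len(included) >= 2:
        res_t1 = wilcoxon_signed_rank(
            included["mean_t1_early"].to_numpy(), included["mean_t1_late"].to_numpy()
        )
        res_pct = wilcoxon_signed_rank(
            included["pct_success_early"].to_numpy(),
            included["pct_success_late"].to_numpy(),
        )
        stats_out["early_vs_late_t1"] = dataclasses.asdict(res_t1)
        stats_out["early_vs_late_pct_success"] = dataclasses.asdict(res_pct)

    bundle = {
        "version": __version__,
        "config_hash": config.hash(),
        "missing_trials": [list(k) for k in session.missing],
        "filter_reports": {
            f"{fid}:{trial}": dataclasses.asdict(rep)
            for (fid, trial), rep in sorted(reports.items())
        },
        "overrides": config.overrides,
        "group_stats": stats_out,
    }
    with open(out_dir / "group_stats.json", "w") as fh:
        json.dump(bundle, fh, indent=2, sort_keys=True)
    with open(out_dir / "run.log", "w") as fh:
        fh.write(header)
        fh.write(f"tracks={len(session.tracks)} missing={len(session.missing)}\n")
        for key, rep in sorted(reports.items()):
            fh.write(f"{key}: {rep}\n")
    return bundle
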