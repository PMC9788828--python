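"""Three-step pose-track prefilter: likelihood gate, jump filter, spline fill.

The stages run in a fixed order. First, frames whose keypoint likelihood
falls below a confidence threshold (default 0.999) have their coordinates
masked. Second, Euclidean step distances between consecutive still-valid
frames are pooled across every track of the dataset, and steps in the top
tail (default 5%) of that pooled distribution mark the second frame of the
pair as an anomaly. Third, interior gaps are filled with a natural cubic
spline through the remaining points; leading and trailing gaps are never
extrapolated and stay missing.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
from scipy.interpolate import CubicSpline

from .trackio import PoseTrack, SessionTable

__all__ = [
    "FilterReport",
    "PreprocessConfig",
    "likelihood_gate",
    "jump_filter",
    "spline_interpolate",
    "preprocess_pipeline",
]

DEFAULT_LIKELIHOOD_THRESHOLD = 0.999
DEFAULT_JUMP_QUANTILE = 0.05


@dataclass
class FilterReport:
    """Per-track frame bookkeeping for one keypoint.

    For a track with no missing coordinates on input,
    ``n_interpolated + n_residual_missing == n_gated + n_anomalies``.
    """

    n_gated: int = 0
    n_anomalies: int = 0
    n_interpolated: int = 0
    n_residual_missing: int = 0

    def __add__(self, other: "FilterReport") -> "FilterReport":
        return FilterReport(
            self.n_gated + other.n_gated,
            self.n_anomalies + other.n_anomalies,
            self.n_interpolated + other.n_interpolated,
            self.n_residual_missing + other.n_residual_missing,
        )


@dataclass
class PreprocessConfig:
    likelihood_threshold: float = DEFAULT_LIKELIHOOD_THRESHOLD
    jump_quantile: float = DEFAULT_JUMP_QUANTILE
    keypoints: tuple[str, ...] = ("head",)


def _missing_mask(track: PoseTrack, keypoint: str) -> np.ndarray:
    xy = track.xy(keypoint).to_numpy(float)
    return np.isnan(xy).any(axis=1)


def likelihood_gate(
    track: PoseTrack, keypoint: str, threshold: float = DEFAULT_LIKELIHOOD_THRESHOLD
) -> tuple[PoseTrack, FilterReport]:
    """Mask coordinates of frames whose likelihood is below ``threshold``.

    Likelihood values themselves are retained; only x and y become missing.
    """
    if not 0 < threshold <= 1:
        raise ValueError(f"threshold must be in (0,1], got {threshold}")
    out = track.copy()
    lik = out.likelihood(keypoint).to_numpy(float)
    already = _missing_mask(out, keypoint)
    gate = (lik < threshold) & ~already
    out.data.loc[gate, (keypoint, "x")] = np.nan
    out.data.loc[gate, (keypoint, "y")] = np.nan
    return out, FilterReport(n_gated=int(gate.sum()))


def _step_distances(track: PoseTrack, keypoint: str) -> tuple[np.ndarray, np.ndarray]:
    """Distances between consecutive non-missing frames.

    Returns (distances, index of the second frame of each pair). A missing
    frame breaks contiguity: no distance is computed across it.
    """
    xy = track.xy(keypoint).to_numpy(float)
    valid = ~np.isnan(xy).any(axis=1)
    pair = valid[1:] & valid[:-1]
    d = np.hypot(xy[1:, 0] - xy[:-1, 0], xy[1:, 1] - xy[:-1, 1])
    idx = np.where(pair)[0] + 1
    return d[pair], idx


def jump_filter(
    tracks: Iterable[PoseTrack],
    keypoint: str = "head",
    quantile: float = DEFAULT_JUMP_QUANTILE,
) -> tuple[list[PoseTrack], list[FilterReport]]:
    """Mask teleport-like jump anomalies using a pooled distance quantile.

    Step distances are pooled across *all* supplied tracks; steps strictly
    greater than the pooled (1 - quantile) sample quantile (linear
    interpolation between order statistics) mark the second frame of the
    pair as missing. Single pass; ties at the threshold are not flagged.
    """
    if not 0 < quantile < 1:
        raise ValueError(f"quantile must be in (0,1), got {quantile}")
    tracks = [t.copy() for t in tracks]
    pooled = []
    per_track: list[tuple[np.ndarray, np.ndarray]] = []
    for t in tracks:
        d, idx = _step_distances(t, keypoint)
        per_track.append((d, idx))
        pooled.append(d)
    pool = np.concatenate(pooled) if pooled else np.array([])
    if pool.size == 0:
        raise ValueError("no distances: fewer than 2 non-missing frames in every track")
    threshold = float(np.quantile(pool, 1.0 - quantile))
    reports = []
    for t, (d, idx) in zip(tracks, per_track):
        flag = idx[d > threshold]
        t.data.loc[t.data.index[flag], (keypoint, "x")] = np.nan
        t.data.loc[t.data.index[flag], (keypoint, "y")] = np.nan
        reports.append(FilterReport(n_anomalies=int(flag.size)))
    return tracks, reports


def spline_interpolate(
    track: PoseTrack, keypoint: str = "head"
) -> tuple[PoseTrack, FilterReport]:
    """Fill interior gaps with a natural cubic spline; never extrapolate.

    Each coordinate is splined independently through its non-missing
    (frame, value) points, with natural boundary conditions (zero second
    derivative at the end knots). Leading/trailing missing runs remain
    missing. Tracks with fewer than 4 valid frames pass through unchanged.
    """
    out = track.copy()
    missing = _missing_mask(out, keypoint)
    n_missing = int(missing.sum())
    valid = ~missing
    if valid.sum() < 4 or n_missing == 0:
        return out, FilterReport(n_residual_missing=n_missing)

    frames = np.asarray(out.data.index, dtype=float)
    first, last = np.where(valid)[0][[0, -1]]
    interior = missing.copy()
    interior[: first + 1] = False
    interior[last:] = False

    for coord in ("x", "y"):
        col = out.data[(keypoint, coord)].to_numpy(float)
        cs = CubicSpline(frames[valid], col[valid], bc_type="natural")
        col[interior] = cs(frames[interior])
        out.data[(keypoint, coord)] = col

    n_filled = int(interior.sum())
    return out, FilterReport(n_interpolated=n_filled, n_residual_missing=n_missing - n_filled)


def preprocess_pipeline(
    session: SessionTable, config: PreprocessConfig | Mapping | None = None
) -> tuple[SessionTable, dict[tuple[str, int], FilterReport]]:
    """Gate -> pooled jump filter -> spline, on every track of a session.

    The jump-distance pool excludes frames already masked by the gate (the
    filters run strictly in order). Reports are per (fish, trial), summed
    over the configured keypoints.
    """
    if config is None:
        config = PreprocessConfig()
    elif isinstance(config, Mapping):
        config = PreprocessConfig(**dict(config))

    keys = sorted(session.tracks)
    tracks = [session.tracks[k] for k in keys]
    reports = {k: FilterReport() for k in keys}

    for kp in config.keypoints:
        gated = []
        for k, t in zip(keys, tracks):
            g, rep = likelihood_gate(t, kp, config.likelihood_threshold)
            reports[k] = reports[k] + rep
            gated.append(g)
        jumped, jreps = jump_filter(gated, kp, config.jump_quantile)
        for k, rep in zip(keys, jreps):
            reports[k] = reports[k] + rep
        tracks = []
        for k, t in zip(keys, jumped):
            s, rep = spline_interpolate(t, kp)
            reports[k] = reports[k] + rep
            tracks.append(s)

    out = SessionTable(
        tracks=dict(zip(keys, tracks)),
        meta=dict(session.meta),
        missing=list(session.missing),
    )
    return out, reports
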