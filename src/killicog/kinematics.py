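"""Frame-level kinematics: upward velocity, rolling means, angles, compass bins.

All coordinates are in image convention (y grows downward), so upward
velocity is the negated y finite difference times the frame rate, and
displacement angles are measured on upward-positive axes: 0 deg points
rightward, 90 deg points straight up toward the water surface.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .trackio import PoseTrack

__all__ = [
    "KinematicsSeries",
    "CompassHistogram",
    "vertical_velocity",
    "rolling_velocity",
    "winsorized_mean_velocity",
    "displacement_angle",
    "compass_histogram",
    "velocity_heatmap_matrix",
]

DEFAULT_ROLLING_WINDOW = 20
DEFAULT_WINSOR_CAP = 0.15
DEFAULT_COMPASS_BIN = 20.0
DEFAULT_HEATMAP_CLIP_HIGH = 0.07
DEFAULT_HEATMAP_CLIP_LOW = 0.10


@dataclass
class KinematicsSeries:
    """Per-frame kinematics for one trial.

    v_up is upward velocity in px/s (positive toward the surface),
    v_up_rolled its centered rolling mean, dist_food the Euclidean distance
    to the food-drop site in px. All series share the track's frame index;
    entries are NaN where inputs are missing or the rolling window is
    incomplete.
    """

    t: pd.Series
    v_up: pd.Series
    v_up_rolled: pd.Series | None = None
    dist_food: pd.Series | None = None
    fps: float = 20.0


@dataclass
class CompassHistogram:
    """Angular frequency distribution with fixed-width bins over [0, 360)."""

    bin_edges: np.ndarray
    counts: np.ndarray
    group: str = ""

    @property
    def midpoints(self) -> np.ndarray:
        return (self.bin_edges[:-1] + self.bin_edges[1:]) / 2.0


def vertical_velocity(track: PoseTrack, keypoint: str = "head") -> KinematicsSeries:
    """Instantaneous upward velocity: ``v_up[i] = -(y[i] - y[i-1]) * fps``.

    The first frame is undefined; a missing coordinate makes both adjacent
    velocities missing.
    """
    y = track.xy(keypoint)["y"]
    v_up = -y.diff() * track.fps
    t = pd.Series(track.times(), index=track.data.index)
    return KinematicsSeries(t=t, v_up=v_up, fps=track.fps)


def rolling_velocity(
    series: KinematicsSeries, window: int = DEFAULT_ROLLING_WINDOW, center: bool = True
) -> KinematicsSeries:
    """Centered moving average of v_up over ``window`` frames.

    Frames whose window is incomplete (edges, or any missing input inside
    the window) are left missing.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    if window > len(series.v_up):
        warnings.warn("rolling window longer than series; all values missing", stacklevel=2)
    rolled = series.v_up.rolling(window, center=center, min_periods=window).mean()
    rolled[series.v_up.isna()] = np.nan
    return KinematicsSeries(
        t=series.t, v_up=series.v_up, v_up_rolled=rolled,
        dist_food=series.dist_food, fps=series.fps,
    )


def _pooled_rolled(trials: dict[int, KinematicsSeries]) -> np.ndarray:
    vals = []
    for kin in trials.values():
        if kin.v_up_rolled is None:
            raise ValueError("rolling velocity not computed for a trial")
        vals.append(kin.v_up_rolled.to_numpy(float))
    pool = np.concatenate(vals) if vals else np.array([])
    return pool[~np.isnan(pool)]


def winsorized_mean_velocity(
    trials: dict[int, KinematicsSeries], cap: float = DEFAULT_WINSOR_CAP
) -> float:
    """Mean rolling velocity of one animal after two-sided winsorization.

    Rolling velocities are pooled over all frames of all the animal's
    trials; values beyond the ``cap`` / ``1-cap`` percentiles (linear
    interpolation between order statistics) are set to those percentile
    values before averaging. Caps extreme velocity estimates from
    low-likelihood frames.
    """
    if not 0 <= cap < 0.5:
        raise ValueError(f"cap must be in [0, 0.5), got {cap}")
    pool = _pooled_rolled(trials)
    if pool.size == 0:
        raise ValueError("empty velocity pool")
    lo, hi = np.percentile(pool, [100 * cap, 100 * (1 - cap)])
    return float(np.mean(np.clip(pool, lo, hi)))


def displacement_angle(
    track: PoseTrack, t_start: float = 2.0, t_end: float = 9.0, keypoint: str = "head"
) -> float:
    """Direction of travel between two trial times, in degrees in [0, 360).

    Positions are taken at the frame nearest each requested second. The
    angle uses upward-positive axes: 0 = rightward, 90 = straight up toward
    the surface. Returns NaN when either endpoint position is missing.
    """
    frames = np.asarray(track.data.index, dtype=float)
    xy = track.xy(keypoint).to_numpy(float)
    i0 = int(np.argmin(np.abs(frames - t_start * track.fps)))
    i1 = int(np.argmin(np.abs(frames - t_end * track.fps)))
    p0, p1 = xy[i0], xy[i1]
    if np.isnan(p0).any() or np.isnan(p1).any():
        return float("nan")
    dx = p1[0] - p0[0]
    dup = -(p1[1] - p0[1])  # image y grows downward
    return float(np.degrees(np.arctan2(dup, dx)) % 360.0)


def compass_histogram(
    angles, bin_width: float = DEFAULT_COMPASS_BIN, group: str = ""
) -> CompassHistogram:
    """Bin displacement angles into fixed-width wedges covering [0, 360)."""
    if 360.0 % bin_width:
        raise ValueError(f"bin_width must divide 360, got {bin_width}")
    a = np.asarray(list(angles), dtype=float)
    a = a[~np.isnan(a)] % 360.0
    edges = np.arange(0.0, 360.0 + bin_width, bin_width)
    counts, _ = np.histogram(a, bins=edges)
    return CompassHistogram(bin_edges=edges, counts=counts, group=group)


def velocity_heatmap_matrix(
    trials: dict[int, KinematicsSeries],
    clip_high: float = DEFAULT_HEATMAP_CLIP_HIGH,
    clip_low: float = DEFAULT_HEATMAP_CLIP_LOW,
) -> tuple[pd.DataFrame, tuple[float, float]]:
    """Trial-by-second mean rolling velocity plus heatmap clip bounds.

    Returns the matrix (rows = trial numbers, columns = whole seconds) and
    the animal's pooled (1-clip_high) / clip_low percentile bounds as
    plotting metadata. Values in the matrix are NOT altered by the bounds.
    """
    rows = {}
    for trial, kin in sorted(trials.items()):
        if kin.v_up_rolled is None:
            raise ValueError("rolling velocity not computed for a trial")
        sec = np.floor(kin.t.to_numpy(float)).astype(int)
        rows[trial] = pd.Series(kin.v_up_rolled.to_numpy(float)).groupby(sec).mean()
    mat = pd.DataFrame(rows).T.sort_index()
    mat.index.name = "trial"
    mat.columns.name = "second"
    pool = _pooled_rolled(trials)
    hi = float(np.percentile(pool, 100 * (1 - clip_high)))
    lo = float(np.percentile(pool, 100 * clip_low))
    return mat, (lo, hi)
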