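"""Associative-learning quantification.

Food is dropped at a fixed site a few seconds after a red cue light turns
on. A trial counts as a successful association when the fish initiates its
first surface-bound trajectory (latency ``t1``) inside the closed window
between light onset (2 s) and food arrival (9 s). ``t1`` is extracted
automatically by combining per-animal velocity bursts (rolling upward
velocity above a fraction of the animal's velocity range) with arrivals at
the surface (entering a radius around the food-drop site), or manually from
per-second score sheets.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .kinematics import KinematicsSeries
from .trackio import PoseTrack, TrialMeta

__all__ = [
    "T1Result",
    "SessionSummary",
    "FoodDropSite",
    "locate_food_drop",
    "distance_to_site",
    "surface_arrivals",
    "velocity_bursts",
    "first_surface_bound_time",
    "trial_success",
    "learning_index",
    "manual_t1",
    "session_summary",
]

DEFAULT_SURFACE_RADIUS = 125.0  # px; allowed range in practice 100-150
DEFAULT_BURST_FRACTION = 0.75  # threshold at 75% of the velocity range
DEFAULT_MIN_EATING_TRIALS = 3
EARLY_TRIALS = tuple(range(1, 8))
LATE_TRIALS = tuple(range(11, 18))


@dataclass
class FoodDropSite:
    x: float
    y: float
    n_videos_used: int


@dataclass
class T1Result:
    fish_id: str
    trial_number: int
    t1: float
    success: bool
    method: str = "auto"
    burst_threshold_used: float = float("nan")
    surface_threshold_used: float = float("nan")


@dataclass
class SessionSummary:
    """Per-fish aggregate of early (trials 1-7) vs late (trials 11-17) blocks."""

    fish_id: str
    mean_t1_early: float
    mean_t1_late: float
    pct_success_early: float
    pct_success_late: float
    learning_index_k2: float
    learning_index_k3: float
    learning_index_k4: float
    n_trials_used_early: int
    n_trials_used_late: int
    winsorized_mean_velocity: float = float("nan")
    included: bool = True
    n_eating_trials: int = 0
    extras: dict = field(default_factory=dict)


def locate_food_drop(tracks: dict[int, PoseTrack]) -> FoodDropSite:
    """Food-drop site for one animal.

    Per video, takes the coordinate at the maximum food-drop likelihood;
    the site is the mean of those per-video coordinates. Videos whose
    food-drop likelihood is zero (or missing) throughout are excluded.
    """
    coords = []
    for track in tracks.values():
        lik = track.likelihood("food_drop").to_numpy(float)
        if np.all(np.isnan(lik)) or np.nanmax(lik) <= 0:
            continue
        i = int(np.nanargmax(lik))
        xy = track.xy("food_drop").to_numpy(float)[i]
        if np.isnan(xy).any():
            continue
        coords.append(xy)
    if not coords:
        raise ValueError("no video with a usable food_drop likelihood")
    mean = np.mean(coords, axis=0)
    return FoodDropSite(x=float(mean[0]), y=float(mean[1]), n_videos_used=len(coords))


def distance_to_site(
    track: PoseTrack, site: FoodDropSite, keypoint: str = "head"
) -> pd.Series:
    """Per-frame Euclidean distance (px) from a keypoint to the food-drop site."""
    xy = track.xy(keypoint)
    return np.hypot(xy["x"] - site.x, xy["y"] - site.y)


def surface_arrivals(
    dist_food: pd.Series, radius: float = DEFAULT_SURFACE_RADIUS, fps: float = 20.0
) -> list[float]:
    """Times (s) at which the fish arrives at the surface.

    A frame is "at the surface" when its distance to the food-drop site is
    at most ``radius``. Contiguous at-surface runs collapse to the time of
    their first frame.
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    at = (dist_food.to_numpy(float) <= radius).astype(int)
    starts = np.where(np.diff(np.concatenate([[0], at])) == 1)[0]
    frames = np.asarray(dist_food.index, dtype=float)
    return [float(frames[i] / fps) for i in starts]


def velocity_bursts(
    trials: dict[int, KinematicsSeries], fraction: float = DEFAULT_BURST_FRACTION
) -> tuple[dict[int, list[tuple[float, float]]], float]:
    """Per-trial high-velocity burst intervals for one animal.

    The burst threshold sits at ``v_min + fraction * (v_max - v_min)`` of
    the animal's pooled rolling-velocity range (default: top quarter of the
    range). Bursts are maximal runs of frames strictly above the threshold,
    reported as (start_s, end_s) of their first and last frame.
    """
    if not 0 < fraction < 1:
        raise ValueError(f"fraction must be in (0,1), got {fraction}")
    pool = []
    for kin in trials.values():
        if kin.v_up_rolled is None:
            raise ValueError("rolling velocity not computed for a trial")
        v = kin.v_up_rolled.to_numpy(float)
        pool.append(v[~np.isnan(v)])
    pool = np.concatenate(pool) if pool else np.array([])
    if pool.size == 0:
        raise ValueError("empty velocity pool")
    v_min, v_max = float(pool.min()), float(pool.max())
    threshold = v_min + fraction * (v_max - v_min)

    bursts: dict[int, list[tuple[float, float]]] = {}
    for trial, kin in trials.items():
        v = kin.v_up_rolled.to_numpy(float)
        above = np.zeros(len(v), dtype=int)
        above[~np.isnan(v)] = (v[~np.isnan(v)] > threshold).astype(int)
        d = np.diff(np.concatenate([[0], above, [0]]))
        starts = np.where(d == 1)[0]
        ends = np.where(d == -1)[0] - 1
        frames = np.asarray(kin.t.index, dtype=float)
        bursts[trial] = [
            (float(frames[s] / kin.fps), float(frames[e] / kin.fps))
            for s, e in zip(starts, ends)
        ]
    return bursts, float(threshold)


def _interval_distance(t: float, interval: tuple[float, float]) -> float:
    lo, hi = interval
    if lo <= t <= hi:
        return 0.0
    return min(abs(t - lo), abs(t - hi))


def first_surface_bound_time(
    bursts: list[tuple[float, float]],
    arrivals: list[float],
    timing: TrialMeta,
    at_surface_at_start: bool = False,
) -> float:
    """Latency t1 (s) of the first surface-bound trajectory in one trial.

    Edge rules, checked in order: a fish already at the surface on the
    first analyzed frame gets t1 = 0; a fish that never arrives at the
    surface gets t1 = trial_end_s. Otherwise t1 is the start time of the
    velocity burst closest in time to the first arrival (distance 0 when
    the arrival falls inside the burst; ties broken toward the earlier
    burst). With no burst at all, t1 falls back to the arrival time.
    """
    if at_surface_at_start:
        return 0.0
    if not arrivals:
        return float(timing.trial_end_s)
    a = min(arrivals)
    if not bursts:
        return float(a)
    best = min(bursts, key=lambda b: (_interval_distance(a, b), b[0]))
    return float(best[0])


def trial_success(t1: float, timing: TrialMeta) -> bool:
    """True iff t1 lies in the closed cue-to-food window [light_on, food_drop].

    The window is conservative: actual food arrival varied a couple of
    seconds past the nominal drop time.
    """
    if np.isnan(t1):
        return False
    return timing.light_on_s <= t1 <= timing.food_drop_s


def learning_index(successes, k: int = 2, trial_numbers=None) -> float:
    """Inverse of the first trial number starting k consecutive successes.

    Returns 0 when the animal never achieves such a run (a "never learned"
    animal scores below any learner). Trials are numbered from 1 unless
    ``trial_numbers`` supplies explicit labels.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    flags = [bool(s) for s in successes]
    numbers = list(trial_numbers) if trial_numbers is not None else list(
        range(1, len(flags) + 1)
    )
    run = 0
    for i, s in enumerate(flags):
        run = run + 1 if s else 0
        if run >= k:
            return 1.0 / numbers[i - k + 1]
    return 0.0


def manual_t1(scores: pd.DataFrame, timing: TrialMeta | None = None) -> T1Result:
    """t1 from a per-second manual score sheet.

    Finds the first second the fish is at the surface, then backtracks
    through the maximal unbroken run of upward flags ending at that second:
    a pause (upward = 0 for at least one second) during the ascent restarts
    the run, so only the final continuous ascent counts. A fish that never
    reaches the surface gets t1 = trial_end_s.
    """
    timing = timing or TrialMeta(fish_id="", trial_number=0)
    secs = scores["second"].to_numpy()
    up = scores["upward"].to_numpy(int)
    at = scores["at_surface"].to_numpy(int)
    surf = np.where(at == 1)[0]
    if surf.size == 0:
        t1 = float(timing.trial_end_s)
    else:
        j = int(surf[0])
        i = j
        while i > 0 and up[i - 1] == 1:
            i -= 1
        t1 = float(secs[i])
    return T1Result(
        fish_id="", trial_number=0, t1=t1,
        success=trial_success(t1, timing), method="manual",
    )


def _block_stats(
    results: dict[int, T1Result], block: tuple[int, ...]
) -> tuple[float, float, int]:
    """(mean t1, % success, n trials with a defined t1) over a trial block.

    The percent-success denominator stays at the block size (7) even when a
    trial's t1 is missing; the count of trials actually used is reported
    alongside.
    """
    t1s = [results[t].t1 for t in block if t in results and not np.isnan(results[t].t1)]
    succ = sum(1 for t in block if t in results and results[t].success)
    mean_t1 = float(np.mean(t1s)) if t1s else float("nan")
    pct = 100.0 * succ / len(block)
    return mean_t1, pct, len(t1s)


def session_summary(
    fish_id: str,
    results: dict[int, T1Result],
    meta: dict[int, TrialMeta] | None = None,
    winsorized_velocity: float = float("nan"),
    min_eating_trials: int = DEFAULT_MIN_EATING_TRIALS,
) -> SessionSummary:
    """Per-fish early/late aggregates, learning indices and the eating rule.

    Animals that ate in fewer than ``min_eating_trials`` trials are flagged
    excluded (likely unmotivated or unhealthy) but still summarized.
    """
    mean_e, pct_e, n_e = _block_stats(results, EARLY_TRIALS)
    mean_l, pct_l, n_l = _block_stats(results, LATE_TRIALS)
    ordered = sorted(results)
    flags = [results[t].success for t in ordered]
    li = {k: learning_index(flags, k=k, trial_numbers=ordered) for k in (2, 3, 4)}
    n_eat = sum(1 for t, m in (meta or {}).items() if m.ate)
    return SessionSummary(
        fish_id=fish_id,
        mean_t1_early=mean_e,
        mean_t1_late=mean_l,
        pct_success_early=pct_e,
        pct_success_late=pct_l,
        learning_index_k2=li[2],
        learning_index_k3=li[3],
        learning_index_k4=li[4],
        n_trials_used_early=n_e,
        n_trials_used_late=n_l,
        winsorized_mean_velocity=winsorized_velocity,
        included=(meta is None) or (n_eat >= min_eating_trials),
        n_eating_trials=n_eat,
    )
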