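"""Synthetic inputs with ground truth for every pipeline stage.

The track generator emulates the conditioning assay: a fish wanders near
the tank bottom (with occasional darting moves), then at a trial-dependent
true latency executes a decelerating ballistic ascent to just under the
food-drop site and holds near the surface. Measurement artifacts —
Gaussian keypoint noise, likelihood dropouts, single-frame teleports — are
injected at controlled rates and recorded as ground truth. Companion
generators produce idealized manual score sheets, Bernoulli missed-feeding
logs, right-censored Gompertz lifespans, and DEG tables with a controllable
sex-by-diet joint distribution and expression-dependent structure.

All generators are pure functions of (config, seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .trackio import PoseTrack, SessionTable, TrialMeta

__all__ = [
    "TrackSimConfig",
    "SyntheticTruth",
    "default_latency_curve",
    "simulate_tracks",
    "simulate_manual_scores",
    "simulate_feeder_logs",
    "simulate_lifespans",
    "simulate_deg_tables",
]


def default_latency_curve(n_trials: int = 17) -> np.ndarray:
    """Geometric decay of the true surface-bound latency from 12 s to ~3.7 s.

    Early trials start above the food-arrival time (failures); from around
    trial 4 the latency enters the 2-9 s success window, mimicking an animal
    that acquires the light-food association over the first training day.
    """
    k = np.arange(n_trials)
    return 3.0 + 9.0 * 0.85**k


@dataclass
class TrackSimConfig:
    """Study-condition defaults for the track generator.

    Sixteen fish, 17 trials at 20 frames/s over 18 s; cue light at 2 s,
    nominal food drop at 9 s. Artifact rates default to 5 px keypoint
    noise, 5% likelihood dropouts and 1% teleports.
    """

    n_fish: int = 16
    n_trials: int = 17
    fps: float = 20.0
    trial_len_s: float = 18.0
    tank_w: float = 800.0
    tank_h: float = 600.0
    light_on_s: float = 2.0
    food_drop_s: float = 9.0
    latency_curve: np.ndarray | None = None
    latency_jitter_s: float = 0.4
    noise_sd: float = 5.0
    dropout_p: float = 0.05
    teleport_p: float = 0.01
    ascent_s: float = 1.5
    eat_s: float = 3.0  # time spent at the surface before diving back down
    dive_s: float = 2.5
    surface_radius: float = 125.0
    dart_p: float = 0.06
    pause_p: float = 0.0  # chance a manual sheet gets a mid-ascent pause
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("dropout_p", "teleport_p", "dart_p", "pause_p"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0,1], got {v}")
        if self.surface_radius * 2 > self.tank_h:
            raise ValueError("impossible geometry: surface radius exceeds half the tank height")


@dataclass
class SyntheticTruth:
    """Ground truth per (fish_id, trial_number)."""

    latency_s: dict[tuple[str, int], float] = field(default_factory=dict)
    arrival_s: dict[tuple[str, int], float] = field(default_factory=dict)
    dropout_frames: dict[tuple[str, int], np.ndarray] = field(default_factory=dict)
    teleport_frames: dict[tuple[str, int], np.ndarray] = field(default_factory=dict)
    pause_second: dict[tuple[str, int], int | None] = field(default_factory=dict)
    config: TrackSimConfig | None = None
    seed: int = 0


def _wander(rng, n, center, sd, theta=0.08, dart_p=0.0, dart_lo=15.0, dart_hi=30.0,
            start=None):
    """Mean-reverting 2-D wander with occasional darting moves."""
    pos = np.empty((n, 2))
    pos[0] = center if start is None else start
    for i in range(1, n):
        step = theta * (center - pos[i - 1]) + rng.normal(0.0, sd, 2)
        if dart_p and rng.random() < dart_p:
            ang = rng.uniform(0, 2 * math.pi)
            mag = rng.uniform(dart_lo, dart_hi)
            step = step + mag * np.array([math.cos(ang), math.sin(ang)])
        pos[i] = pos[i - 1] + step
    return pos


def _ascent_path(p0, p1, n_frames):
    """Decelerating straight-line ascent: fast initiation, glide to rest."""
    tau = np.linspace(0, 1, n_frames, endpoint=False)
    prog = 2 * tau - tau**2  # constant deceleration from v_max to 0
    return p0 + prog[:, None] * (np.asarray(p1) - np.asarray(p0))


def _trial_track(rng, cfg: TrackSimConfig, latency_s: float):
    n = int(round(cfg.trial_len_s * cfg.fps))
    site = np.array([cfg.tank_w / 2.0, 0.06 * cfg.tank_h])
    light = np.array([0.08 * cfg.tank_w, 0.05 * cfg.tank_h])
    bottom = np.array([cfg.tank_w / 2.0 + rng.uniform(-80, 80), 0.58 * cfg.tank_h])
    target = site + np.array([rng.uniform(-40, 40), 0.45 * cfg.surface_radius])

    lat_f = int(round(latency_s * cfg.fps))
    asc_f = int(round(cfg.ascent_s * cfg.fps))
    lat_f = min(lat_f, n)

    head = np.empty((n, 2))
    pre = _wander(rng, max(lat_f, 1), bottom, sd=4.0, dart_p=cfg.dart_p)
    head[:lat_f] = pre[:lat_f]
    if lat_f < n:
        n_asc = min(asc_f, n - lat_f)
        start = head[lat_f - 1] if lat_f > 0 else bottom
        head[lat_f : lat_f + n_asc] = _ascent_path(start, target, n_asc)
        # eat at the surface, then dive back down and wander at depth
        eat_f = lat_f + n_asc
        dive_f = min(eat_f + int(round(cfg.eat_s * cfg.fps)), n)
        if dive_f > eat_f:
            head[eat_f:dive_f] = target + rng.normal(0.0, 2.5, (dive_f - eat_f, 2))
        if dive_f < n:
            n_dive = min(int(round(cfg.dive_s * cfg.fps)), n - dive_f)
            head[dive_f : dive_f + n_dive] = _ascent_path(head[dive_f - 1], bottom, n_dive)
            n_post = n - dive_f - n_dive
            if n_post > 0:
                head[dive_f + n_dive :] = _wander(
                    rng, n_post, bottom, sd=4.0, dart_p=cfg.dart_p,
                    start=head[dive_f + n_dive - 1],
                )

    head = head + rng.normal(0.0, cfg.noise_sd, head.shape)

    # likelihood dropouts: low-confidence frames get garbage coordinates
    lik = rng.uniform(0.999, 1.0, n)
    drop = np.where(rng.random(n) < cfg.dropout_p)[0]
    lik[drop] = rng.uniform(0.0, 0.999, drop.size)
    head[drop] = np.column_stack(
        [rng.uniform(0, cfg.tank_w, drop.size), rng.uniform(0, cfg.tank_h, drop.size)]
    )

    # single-frame teleport artifacts at full confidence; neighbors must be
    # clean frames so the jump filter sees both oversized steps
    near_drop = np.unique(np.concatenate([drop - 1, drop, drop + 1]))
    candidates = np.setdiff1d(np.arange(1, n - 1), near_drop)
    tele = candidates[rng.random(candidates.size) < cfg.teleport_p]
    for i in tele:
        ang = rng.uniform(0, 2 * math.pi)
        head[i] = head[i] + 450.0 * np.array([math.cos(ang), math.sin(ang)])

    tail = head + np.array([0.0, 14.0]) + rng.normal(0.0, cfg.noise_sd, head.shape)
    data = {}
    for name, series, lk in (
        ("head", head, lik),
        ("tail", tail, rng.uniform(0.999, 1.0, n)),
        ("food_drop", site + rng.normal(0, 1.0, (n, 2)), rng.uniform(0.999, 1.0, n)),
        ("red_light", light + rng.normal(0, 1.0, (n, 2)), rng.uniform(0.999, 1.0, n)),
    ):
        data[(name, "x")] = series[:, 0]
        data[(name, "y")] = series[:, 1]
        data[(name, "likelihood")] = lk
    df = pd.DataFrame(data, index=pd.RangeIndex(n))
    df.columns = pd.MultiIndex.from_tuples(df.columns)
    arrival = (lat_f + asc_f) / cfg.fps
    return df, drop, tele, min(arrival, cfg.trial_len_s)


def simulate_tracks(config: TrackSimConfig | None = None) -> tuple[SessionTable, SyntheticTruth]:
    """Generate a full conditioning session plus ground truth.

    Deterministic under ``config.seed``. Old/young structure, sexes and the
    eating flag are assigned round-robin so downstream grouping code has
    non-degenerate metadata to work with.
    """
    cfg = config or TrackSimConfig()
    rng = np.random.default_rng(cfg.seed)
    curve = (
        np.asarray(cfg.latency_curve, float)
        if cfg.latency_curve is not None
        else default_latency_curve(cfg.n_trials)
    )
    if curve.size != cfg.n_trials:
        raise ValueError("latency curve length must equal n_trials")
    if np.any((curve < 0) | (curve > cfg.trial_len_s)):
        raise ValueError("latency curve must lie within [0, trial_len_s]")

    session = SessionTable()
    truth = SyntheticTruth(config=cfg, seed=cfg.seed)
    for f in range(cfg.n_fish):
        fish_id = f"fish{f + 1:02d}"
        sex = "M" if f % 2 == 0 else "F"
        age = 55 + 10 * f if f < cfg.n_fish // 2 else 110 + 3 * f
        for trial in range(1, cfg.n_trials + 1):
            lat = float(np.clip(curve[trial - 1] + rng.normal(0, cfg.latency_jitter_s),
                                2.2, cfg.trial_len_s))
            df, drop, tele, arrival = _trial_track(rng, cfg, lat)
            key = (fish_id, trial)
            session.tracks[key] = PoseTrack(
                data=df, fish_id=fish_id, trial_number=trial, fps=cfg.fps
            )
            session.meta[key] = TrialMeta(
                fish_id=fish_id, trial_number=trial, sex=sex, age_days=float(age),
                ate=True, light_on_s=cfg.light_on_s, food_drop_s=cfg.food_drop_s,
                trial_end_s=cfg.trial_len_s,
            )
            truth.latency_s[key] = lat
            truth.arrival_s[key] = arrival
            truth.dropout_frames[key] = drop
            truth.teleport_frames[key] = tele
            truth.pause_second[key] = None
    return session, truth


def simulate_manual_scores(
    truth: SyntheticTruth, key: tuple[str, int], seed: int | None = None
) -> pd.DataFrame:
    """Idealized per-second manual score sheet for one trial.

    Upward flags cover the ascent seconds, at_surface flags start at the
    arrival second, and with probability ``config.pause_p`` a one-second
    pause interrupts the ascent (exercising the restart rule — the post-
    pause run start is then the manual t1).
    """
    cfg = truth.config or TrackSimConfig()
    rng = np.random.default_rng(cfg.seed + 7919 if seed is None else seed)
    lat = truth.latency_s[key]
    arrival = truth.arrival_s[key]
    n_sec = int(cfg.trial_len_s)
    up = np.zeros(n_sec, dtype=int)
    at = np.zeros(n_sec, dtype=int)
    s0, s1 = int(math.floor(lat)), min(int(math.ceil(arrival)), n_sec)
    if lat < cfg.trial_len_s - 1e-9:
        up[s0:max(s1, s0 + 1)] = 1
        leave = min(int(math.ceil(arrival + cfg.eat_s)), n_sec)
        at[min(s1, n_sec - 1):max(leave, s1 + 1)] = 1
    pause = None
    if cfg.pause_p and rng.random() < cfg.pause_p and s0 >= 3:
        # earlier, abandoned ascent separated by a >=1 s pause
        up[s0 - 3 : s0 - 1] = 1
        up[s0 - 1] = 0
        pause = s0 - 1
    truth.pause_second[key] = pause
    return pd.DataFrame({"second": np.arange(n_sec), "upward": up, "at_surface": at})


def simulate_feeder_logs(
    n_feeders: int, days: int, miss_p: float, seed: int = 0, scheduled_per_day: int = 7
) -> pd.DataFrame:
    """Per feeder-day scheduled/confirmed feeding log with Bernoulli misses."""
    if not 0 <= miss_p <= 1:
        raise ValueError("miss_p must be in [0,1]")
    rng = np.random.default_rng(seed)
    rows = []
    for feeder in range(1, n_feeders + 1):
        missed = rng.binomial(scheduled_per_day, miss_p, size=days)
        for day in range(days):
            rows.append(
                (feeder, day + 1, scheduled_per_day, scheduled_per_day - int(missed[day]))
            )
    return pd.DataFrame(rows, columns=["feeder", "day", "scheduled", "confirmed"])


def simulate_lifespans(
    a: float,
    b: float,
    n: int,
    censor_p: float = 0.0,
    time_unit: float = 1.0,
    seed: int = 0,
    sex: str = "",
    diet: str = "",
    cohort: str = "",
) -> pd.DataFrame:
    """Right-censored Gompertz lifespans by inverse-CDF sampling.

    ``a`` and ``b`` are per ``time_unit``; the returned ``lifespan_days``
    column is in days. t = (1/b) ln(1 - (b/a) ln U) for U ~ Uniform(0,1),
    reducing to the exponential when b = 0. A fraction ``censor_p`` of
    animals is censored uniformly before its death time.
    """
    if a <= 0 or b < 0:
        raise ValueError("need a > 0 and b >= 0")
    rng = np.random.default_rng(seed)
    u = rng.uniform(size=n)
    if b == 0:
        t = -np.log(u) / a
    else:
        t = np.log1p(-(b / a) * np.log(u)) / b
    observed = np.ones(n, dtype=int)
    cens = rng.random(n) < censor_p
    t = np.where(cens, t * rng.uniform(size=n), t)
    observed[cens] = 0
    return pd.DataFrame(
        {
            "lifespan_days": t * time_unit,
            "Observed": observed,
            "sex": sex,
            "diet": diet,
            "cohort": cohort,
        }
    )


def simulate_deg_tables(
    n_genes: int,
    sex_frac: float = 0.1,
    diet_frac: float = 0.05,
    planted_enrichment: float | None = None,
    expr_dependence: float = 0.0,
    expr_distribution: str = "loguniform",
    na_frac: float = 0.0,
    alpha: float = 0.05,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Paired sex/diet DE tables with a planted joint significance structure.

    ``planted_enrichment`` is P(sex DEG | diet DEG); None means
    independence (P = sex_frac). The complementary conditional is adjusted
    to keep the marginal sex-DEG fraction, and an inconsistent joint
    specification raises. ``expr_dependence`` > 0 biases diet-DEG status
    toward high-expression genes (stressing the expression matching).
    Mean expression spans four orders of magnitude; the default
    "loguniform" keeps the matching density constant across that range,
    while "lognormal" has sparse tails where a relative expression window
    can legitimately come up empty.
    """
    for name, v in (("sex_frac", sex_frac), ("diet_frac", diet_frac), ("na_frac", na_frac)):
        if not 0 <= v <= 1:
            raise ValueError(f"{name} must be in [0,1]")
    rng = np.random.default_rng(seed)
    genes = np.array([f"g{i:06d}" for i in range(n_genes)])
    if expr_distribution == "loguniform":
        mean_expr = 10.0 ** rng.uniform(0.0, 4.0, size=n_genes)
    elif expr_distribution == "lognormal":
        mean_expr = rng.lognormal(mean=3.0, sigma=1.5, size=n_genes)
    else:
        raise ValueError(f"unknown expr_distribution {expr_distribution!r}")

    n_diet = int(round(diet_frac * n_genes))
    if expr_dependence > 0:
        ranks = pd.Series(mean_expr).rank().to_numpy()
        w = ranks**expr_dependence
        diet_idx = rng.choice(n_genes, size=n_diet, replace=False, p=w / w.sum())
    else:
        diet_idx = rng.choice(n_genes, size=n_diet, replace=False)
    is_diet = np.zeros(n_genes, dtype=bool)
    is_diet[diet_idx] = True

    p_given_diet = sex_frac if planted_enrichment is None else planted_enrichment
    if diet_frac < 1:
        p_given_not = (sex_frac - p_given_diet * diet_frac) / (1 - diet_frac)
    else:
        p_given_not = 0.0
    if not (0 <= p_given_diet <= 1 and 0 <= p_given_not <= 1):
        raise ValueError(
            "inconsistent joint specification: conditional sex-DEG probabilities "
            f"({p_given_diet:.3f}, {p_given_not:.3f}) fall outside [0,1]"
        )
    is_sex = np.where(
        is_diet, rng.random(n_genes) < p_given_diet, rng.random(n_genes) < p_given_not
    )

    def table(sig: np.ndarray) -> pd.DataFrame:
        padj = np.where(
            sig, rng.uniform(0, alpha, n_genes), rng.uniform(alpha, 1, n_genes)
        )
        na = rng.random(n_genes) < na_frac
        padj = np.where(na, np.nan, padj)
        lfc = rng.normal(0, 0.5, n_genes) + np.where(sig, rng.choice([-2.0, 2.0], n_genes), 0)
        p = padj * rng.uniform(0.2, 1.0, n_genes)
        return pd.DataFrame(
            {
                "gene_id": genes,
                "log2fc": lfc,
                "p": p,
                "padj": padj,
                "mean_expr": mean_expr,
            }
        )

    return table(is_sex), table(is_diet)
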