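"""Censored lifespan analysis: Kaplan-Meier medians, log-rank, Gompertz MLE.

The Gompertz mortality law h(t) = a * exp(b t) separates a baseline hazard
("frailty", a) from the exponential time coefficient ("rate of aging", b).
Both parameters scale with the chosen time unit; fits here take an explicit
``time_unit`` (days per unit) and also report day-scale values, since a
slope quoted against 27-day hazard bins is 27 times the per-day slope.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test
from scipy import optimize
from scipy import stats as sps

from .stats import TestResult, round_half_up

__all__ = [
    "GompertzFit",
    "HazardCurve",
    "records_from_frame",
    "km_median",
    "percent_extension",
    "logrank",
    "gompertz_fit",
    "binned_hazard",
]


@dataclass
class GompertzFit:
    """Maximum-likelihood Gompertz parameters for right-censored lifespans."""

    rate_a: float
    shape_b: float
    ci_a: tuple[float, float]
    ci_b: tuple[float, float]
    loglik: float
    time_unit: float
    n: int
    n_events: int
    converged: bool

    @property
    def rate_a_per_day(self) -> float:
        return self.rate_a / self.time_unit

    @property
    def shape_b_per_day(self) -> float:
        return self.shape_b / self.time_unit


@dataclass
class HazardCurve:
    bin_width: float
    midpoints: np.ndarray
    hazard: np.ndarray
    ln_hazard: np.ndarray
    at_risk: np.ndarray
    deaths: np.ndarray


def records_from_frame(df: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """(durations, observed) arrays from a lifespan table.

    Accepts the source-data schema: ``lifespan_days`` and ``Observed``
    (1 = death, 0 = censored); column names are matched case-insensitively.
    """
    cols = {c.lower(): c for c in df.columns}
    dur_col = cols.get("lifespan_days") or cols.get("lifespan") or cols.get("duration")
    obs_col = cols.get("observed") or cols.get("event")
    if dur_col is None or obs_col is None:
        raise ValueError("lifespan table needs lifespan_days and Observed columns")
    t = df[dur_col].to_numpy(float)
    e = df[obs_col].to_numpy(int)
    if (t <= 0).any():
        raise ValueError("lifespans must be positive")
    return t, e


def km_median(durations, observed=None) -> float:
    """Kaplan-Meier median lifespan: earliest time with survival <= 0.5.

    Returns NaN when the survival curve never reaches 0.5 (heavy
    censoring); raises when there is no observed event at all.
    """
    t = np.asarray(durations, float)
    e = np.ones_like(t, dtype=int) if observed is None else np.asarray(observed, int)
    if e.sum() == 0:
        raise ValueError("no observed events")
    km = KaplanMeierFitter().fit(t, e)
    sf = km.survival_function_.iloc[:, 0]
    # earliest time with S <= 0.5; small slack so product round-off at an
    # exact 0.5 step does not push the median to the next event time
    hit = sf[sf <= 0.5 + 1e-9]
    return float(hit.index[0]) if len(hit) else float("nan")


def percent_extension(median_ref: float, median_test: float) -> float:
    """Percent change of the test median over the reference median, 1 decimal."""
    if median_ref <= 0:
        raise ValueError("reference median must be positive")
    return round_half_up(100.0 * (median_test - median_ref) / median_ref, 1)


def logrank(durations_a, observed_a, durations_b, observed_b) -> TestResult:
    """Two-group log-rank test (chi-square, 1 df) with right censoring."""
    res = logrank_test(
        np.asarray(durations_a, float), np.asarray(durations_b, float),
        event_observed_A=np.asarray(observed_a, int),
        event_observed_B=np.asarray(observed_b, int),
    )
    return TestResult(
        float(res.test_statistic), float(res.p_value), "log-rank",
        (len(np.asarray(durations_a)), len(np.asarray(durations_b))), exact=False,
    )


def _gompertz_negloglik(params: np.ndarray, t: np.ndarray, e: np.ndarray) -> float:
    log_a, b = params
    a = np.exp(log_a)
    bt = b * t
    log_h = log_a + bt
    if abs(b) < 1e-12:
        H = a * t
    else:
        H = (a / b) * np.expm1(bt)
    return float(-(e * log_h).sum() + H.sum())


def _hessian(f, x: np.ndarray, eps: float = 1e-5) -> np.ndarray:
    n = x.size
    H = np.empty((n, n))
    for i in range(n):
        for j in range(i, n):
            ei = np.zeros(n); ei[i] = eps
            ej = np.zeros(n); ej[j] = eps
            H[i, j] = H[j, i] = (
                f(x + ei + ej) - f(x + ei - ej) - f(x - ei + ej) + f(x - ei - ej)
            ) / (4 * eps * eps)
    return H


def gompertz_fit(durations, observed=None, time_unit: float = 1.0) -> GompertzFit:
    """Fit h(t) = a exp(b t) to right-censored lifespans by maximum likelihood.

    Times are divided by ``time_unit`` (days per unit) before fitting; the
    log-likelihood is sum over deaths of ln h(t) minus sum over everyone of
    the cumulative hazard H(t) = (a/b)(e^{bt} - 1) (a t in the b -> 0
    limit). The rate is log-parameterized for positivity; 95% CIs come from
    the observed information, on the log scale for the rate.
    """
    t = np.asarray(durations, float) / time_unit
    e = np.ones_like(t, dtype=int) if observed is None else np.asarray(observed, int)
    if e.sum() < 5:
        raise ValueError("need at least 5 observed events for a stable fit")

    # exponential MLE as starting point: a0 = events / total exposure
    a0 = e.sum() / t.sum()
    x0 = np.array([np.log(a0), 0.01])
    res = optimize.minimize(
        _gompertz_negloglik, x0, args=(t, e), method="Nelder-Mead",
        options={"xatol": 1e-10, "fatol": 1e-10, "maxiter": 5000},
    )
    res = optimize.minimize(
        _gompertz_negloglik, res.x, args=(t, e), method="BFGS",
        options={"gtol": 1e-8},
    )
    if not np.isfinite(res.fun):
        raise RuntimeError(f"Gompertz fit failed: {res.message}")
    log_a, b = res.x
    H = _hessian(lambda p: _gompertz_negloglik(p, t, e), res.x)
    try:
        cov = np.linalg.inv(H)
        se_log_a, se_b = np.sqrt(np.maximum(np.diag(cov), 0))
    except np.linalg.LinAlgError:
        se_log_a = se_b = float("nan")
    z = sps.norm.ppf(0.975)
    a = float(np.exp(log_a))
    ci_a = (float(np.exp(log_a - z * se_log_a)), float(np.exp(log_a + z * se_log_a)))
    ci_b = (float(b - z * se_b), float(b + z * se_b))
    return GompertzFit(
        rate_a=a, shape_b=float(b), ci_a=ci_a, ci_b=ci_b,
        loglik=float(-res.fun), time_unit=time_unit,
        n=int(t.size), n_events=int(e.sum()), converged=bool(res.success or res.fun < np.inf),
    )


def binned_hazard(durations, observed=None, bin_width: float = 27.0) -> HazardCurve:
    """Discrete life-table hazard: deaths per bin over at-risk at bin start.

    Censored individuals count as at risk through the bin containing their
    censoring time. The hazard is per bin (multiply midpoint slope
    relations by the bin width when comparing with per-unit Gompertz
    parameters); ln hazard is NaN for empty bins.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    t = np.asarray(durations, float)
    e = np.ones_like(t, dtype=int) if observed is None else np.asarray(observed, int)
    n_bins = int(np.ceil(t.max() / bin_width))
    edges = np.arange(n_bins + 1) * bin_width
    which = np.minimum((t / bin_width).astype(int), n_bins - 1)
    deaths = np.zeros(n_bins)
    exits = np.zeros(n_bins)  # deaths + censorings per bin
    for k, ev in zip(which, e):
        exits[k] += 1
        if ev:
            deaths[k] += 1
    at_risk = t.size - np.concatenate([[0], np.cumsum(exits)[:-1]])
    with np.errstate(divide="ignore", invalid="ignore"):
        hazard = np.where(at_risk > 0, deaths / at_risk, np.nan)
        ln_h = np.where(hazard > 0, np.log(hazard), np.nan)
    mid = (edges[:-1] + edges[1:]) / 2.0
    return HazardCurve(
        bin_width=float(bin_width), midpoints=mid, hazard=hazard,
        ln_hazard=ln_h, at_risk=at_risk, deaths=deaths,
    )
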