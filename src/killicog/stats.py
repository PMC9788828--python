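"""Nonparametric tests, effect sizes, power analysis and feeder statistics.

The Wilcoxon tests report exact p-values on small untied samples and a
tie-corrected normal approximation otherwise; the a-priori sample size for
the two-group Wilcoxon-Mann-Whitney comparison uses the asymptotic relative
efficiency (A.R.E.) method: the continuous two-sample t-test solution is
inflated by 1/ARE of the assumed parent distribution and rounded up.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import optimize
from scipy import stats as sps

__all__ = [
    "TestResult",
    "EffectSize",
    "PrecisionEstimate",
    "FidelitySummary",
    "ARE_TABLE",
    "wilcoxon_signed_rank",
    "wilcoxon_rank_sum",
    "pearson_r",
    "cohens_d_ci",
    "wmw_power",
    "wmw_sample_size",
    "bootstrap_precision",
    "fidelity_summary",
    "round_half_up",
]

SIGNED_RANK_EXACT_MAX = 25
RANK_SUM_EXACT_MAX = 20

#: Asymptotic relative efficiency of the WMW test vs the t-test by parent
#: distribution. "min" is the distribution-free lower bound 0.864.
ARE_TABLE: Mapping[str, float] = {
    "normal": 3.0 / math.pi,
    "uniform": 1.0,
    "logistic": math.pi**2 / 9.0,
    "laplace": 1.5,
    "min": 0.864,
}


@dataclass
class TestResult:
    statistic: float
    p_value: float
    method: str
    n: int | tuple[int, int]
    exact: bool = False


@dataclass
class EffectSize:
    d: float
    ci_low: float
    ci_high: float
    n1: int
    n2: int
    conf: float = 0.95


@dataclass
class PrecisionEstimate:
    n: int
    sd_boot: float
    precision: float
    B: int
    seed: int


@dataclass
class FidelitySummary:
    scheduled: int
    confirmed: int
    pct_confirmed: float
    deviation_histogram: dict[int, int]


def round_half_up(x: float, decimals: int = 1) -> float:
    """Round half away from zero (report convention for percent fields)."""
    factor = 10.0**decimals
    return math.copysign(math.floor(abs(x) * factor + 0.5) / factor, x)


def _has_ties(values: np.ndarray) -> bool:
    return len(np.unique(values)) < len(values)


def wilcoxon_signed_rank(x, y) -> TestResult:
    """Two-tailed Wilcoxon matched-pairs signed-rank test.

    Zero differences are dropped. Exact null distribution when at most
    25 nonzero differences and no ties among their absolute values;
    otherwise the tie-corrected normal approximation.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape:
        raise ValueError("paired samples must have equal length")
    d = x - y
    d = d[d != 0]
    n = d.size
    if n == 0:
        import warnings

        warnings.warn("all paired differences are zero; p = 1", stacklevel=2)
        return TestResult(0.0, 1.0, "wilcoxon signed-rank", 0, exact=False)
    exact = n <= SIGNED_RANK_EXACT_MAX and not _has_ties(np.abs(d))
    res = sps.wilcoxon(d, alternative="two-sided", method="exact" if exact else "approx")
    return TestResult(float(res.statistic), float(res.pvalue), "wilcoxon signed-rank", n, exact)


def wilcoxon_rank_sum(a, b) -> TestResult:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test.

    Exact when n1 + n2 <= 20 without ties; otherwise tie-corrected normal
    approximation (no continuity correction, to match the exact tail on
    untied data as n grows).
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    exact = (a.size + b.size) <= RANK_SUM_EXACT_MAX and not _has_ties(pooled)
    res = sps.mannwhitneyu(
        a, b, alternative="two-sided",
        method="exact" if exact else "asymptotic",
        use_continuity=False,
    )
    return TestResult(
        float(res.statistic), float(res.pvalue), "wilcoxon rank-sum",
        (int(a.size), int(b.size)), exact,
    )


def pearson_r(x, y) -> float:
    """Sample Pearson correlation on pairwise-complete observations."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    keep = ~(np.isnan(x) | np.isnan(y))
    x, y = x[keep], y[keep]
    if x.size < 3:
        raise ValueError("need at least 3 complete pairs")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("correlation undefined for a zero-variance vector")
    return float(sps.pearsonr(x, y).statistic)


def cohens_d_ci(group1, group2, conf: float = 0.95) -> EffectSize:
    """Cohen's d with pooled SD and a t-based confidence interval.

    d = (mean1 - mean2) / s_pooled, with s_pooled from df-weighted group
    variances. CI half-width = t_{(1+conf)/2, n1+n2-2} *
    sqrt((n1+n2)/(n1*n2) + d^2 / (2 (n1+n2))).
    """
    g1 = np.asarray(group1, float)
    g2 = np.asarray(group2, float)
    n1, n2 = g1.size, g2.size
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs at least 2 observations")
    v1, v2 = g1.var(ddof=1), g2.var(ddof=1)
    s_pool = math.sqrt(((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2))
    if s_pool == 0:
        raise ValueError("zero pooled variance; d undefined")
    d = (g1.mean() - g2.mean()) / s_pool
    se = math.sqrt((n1 + n2) / (n1 * n2) + d * d / (2 * (n1 + n2)))
    tcrit = sps.t.ppf((1 + conf) / 2, n1 + n2 - 2)
    return EffectSize(float(d), float(d - tcrit * se), float(d + tcrit * se), n1, n2, conf)


def _t_test_power(m1: float, d: float, alpha: float, ratio: float) -> float:
    """Two-sided two-sample t-test power at continuous per-group sizes."""
    m2 = ratio * m1
    df = m1 + m2 - 2
    ncp = abs(d) * math.sqrt(m1 * m2 / (m1 + m2))
    tcrit = sps.t.ppf(1 - alpha / 2, df)
    upper = sps.nct.sf(tcrit, df, ncp)
    lower = sps.nct.cdf(-tcrit, df, ncp)
    if np.isnan(lower):  # far tail underflows to NaN at fractional df
        lower = 0.0
    return float(upper + lower)


def wmw_power(n1: float, d: float, alpha: float = 0.05, ratio: float = 1.0,
              parent: str = "normal") -> float:
    """Approximate WMW power via the A.R.E.-deflated t-test."""
    are = ARE_TABLE[parent]
    return _t_test_power(n1 * are, d, alpha, ratio)


def wmw_sample_size(
    d: float,
    alpha: float = 0.05,
    power: float = 0.8,
    parent: str = "normal",
    ratio: float = 1.0,
) -> int:
    """Per-group n for a two-tailed Wilcoxon-Mann-Whitney comparison.

    A.R.E. method: solve the continuous two-sample noncentral-t sample size
    for the target power at |d|, inflate by 1/ARE(parent), round up.
    Returns the group-1 size; group 2 is ratio times larger.
    """
    if d == 0:
        raise ValueError("effect size must be nonzero")
    if not 0 < alpha < 1 or not 0 < power < 1:
        raise ValueError("alpha and power must be in (0,1)")
    if power <= alpha:
        raise ValueError("target power must exceed alpha")
    if parent not in ARE_TABLE:
        raise ValueError(f"unknown parent {parent!r}; choose from {sorted(ARE_TABLE)}")
    are = ARE_TABLE[parent]
    f = lambda m: _t_test_power(m, d, alpha, ratio) - power  # noqa: E731
    if f(2.001) >= 0:
        return 2
    m_star = optimize.brentq(f, 2.001, 1e7)
    return max(2, math.ceil(m_star / are))


def bootstrap_precision(masses, B: int = 1000, seed: int = 0) -> PrecisionEstimate:
    """Feeding precision = 1 / (bootstrap SD estimate)^2, in 1/mg^2.

    The SD estimate is the mean sample SD over B ordinary nonparametric
    bootstrap resamples of the per-feeding masses.
    """
    m = np.asarray(masses, float)
    if m.size < 2:
        raise ValueError("need at least 2 mass samples")
    if B < 1:
        raise ValueError("B must be >= 1")
    if np.std(m) == 0:
        raise ValueError("zero-variance sample: precision is infinite")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, m.size, size=(B, m.size))
    sds = m[idx].std(axis=1, ddof=1)
    sd_boot = float(sds.mean())
    return PrecisionEstimate(
        n=int(m.size), sd_boot=sd_boot, precision=1.0 / sd_boot**2, B=B, seed=seed
    )


def fidelity_summary(log: pd.DataFrame) -> FidelitySummary:
    """Feeder fidelity over a per-day scheduled/confirmed log.

    pct_confirmed = 100 * total confirmed / total scheduled (1 decimal,
    half-up); the deviation histogram counts days by scheduled - confirmed.
    """
    for col in ("scheduled", "confirmed"):
        if col not in log.columns:
            raise ValueError(f"feeder log lacks column {col!r}")
    sched = log["scheduled"].to_numpy(int)
    conf = log["confirmed"].to_numpy(int)
    if (sched < 0).any() or (conf < 0).any():
        raise ValueError("negative feeding counts")
    if (conf > sched).any():
        raise ValueError("confirmed feedings exceed scheduled on some day")
    dev = sched - conf
    hist = {int(k): int(v) for k, v in zip(*np.unique(dev, return_counts=True))}
    pct = round_half_up(100.0 * conf.sum() / sched.sum(), 1)
    return FidelitySummary(
        scheduled=int(sched.sum()), confirmed=int(conf.sum()),
        pct_confirmed=pct, deviation_histogram=hist,
    )
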