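"""Wilcoxon tests vs enumeration, effect sizes, power, precision, fidelity."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from killicog.stats import (
    bootstrap_precision,
    cohens_d_ci,
    fidelity_summary,
    pearson_r,
    round_half_up,
    wilcoxon_rank_sum,
    wilcoxon_signed_rank,
    wmw_power,
    wmw_sample_size,
)


def enum_signed_rank_p(d):
    """Two-tailed exact signed-rank p by full enumeration of sign patterns."""
    d = np.asarray(d, float)
    d = d[d != 0]
    r = sps.rankdata(np.abs(d))
    w = r[d > 0].sum()
    ws = np.array(
        [(r * np.array(signs)).sum() for signs in itertools.product([0, 1], repeat=len(d))]
    )
    return min(1.0, 2 * min((ws <= w).mean(), (ws >= w).mean()))


def enum_rank_sum_p(a, b):
    """Two-tailed exact rank-sum p by enumeration of all group labelings."""
    pooled = np.concatenate([a, b])
    r = sps.rankdata(pooled)
    n1 = len(a)
    w = r[:n1].sum()
    ws = np.array(
        [r[list(c)].sum() for c in itertools.combinations(range(len(pooled)), n1)]
    )
    return min(1.0, 2 * min((ws <= w).mean(), (ws >= w).mean()))


class TestWilcoxonSignedRank:
    def test_identical_pairs_give_p_one(self):
        with pytest.warns(UserWarning):
            res = wilcoxon_signed_rank([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.p_value == 1.0

    def test_small_sample_matches_enumeration(self):
        x = np.array([5.1, 3.2, 8.4, 2.2, 9.0, 4.4])
        y = np.array([4.0, 4.1, 6.0, 2.9, 5.5, 4.0])
        res = wilcoxon_signed_rank(x, y)
        assert res.exact
        assert res.p_value == pytest.approx(enum_signed_rank_p(x - y), abs=1e-12)

    @settings(max_examples=150, deadline=None, derandomize=True)
    @given(
        st.lists(
            st.floats(-50, 50).filter(lambda v: abs(v) > 1e-6),
            min_size=3, max_size=8, unique_by=abs,
        )
    )
    def test_exact_p_matches_enumeration_property(self, diffs):
        res = wilcoxon_signed_rank(np.asarray(diffs), np.zeros(len(diffs)))
        assert res.exact
        assert res.p_value == pytest.approx(enum_signed_rank_p(diffs), abs=1e-12)

    def test_large_or_tied_samples_use_approximation(self):
        rng = np.random.default_rng(1)
        x = rng.integers(0, 4, 40).astype(float)
        y = rng.integers(0, 4, 40).astype(float)
        keep = x != y
        res = wilcoxon_signed_rank(x[keep], y[keep])
        assert not res.exact
        assert 0 <= res.p_value <= 1


class TestWilcoxonRankSum:
    def test_identical_groups_give_p_one(self):
        res = wilcoxon_rank_sum([1, 2, 3, 4], [4, 3, 2, 1])
        assert res.p_value == 1.0

    def test_small_groups_match_enumeration(self):
        a = np.array([1.2, 5.5, 2.8, 7.1])
        b = np.array([3.3, 9.9, 8.0, 6.6])
        res = wilcoxon_rank_sum(a, b)
        assert res.exact
        assert res.p_value == pytest.approx(enum_rank_sum_p(a, b), abs=1e-12)

    def test_complete_separation_attains_minimal_p(self):
        a = np.array([1.0, 2.0, 3.0, 4.0])
        b = np.array([10.0, 11.0, 12.0, 13.0])
        res = wilcoxon_rank_sum(a, b)
        # minimal attainable two-tailed p for (4,4): 2 / C(8,4)
        assert res.p_value == pytest.approx(2 / 70, abs=1e-12)
        assert res.p_value == pytest.approx(enum_rank_sum_p(a, b), abs=1e-12)

    @settings(max_examples=150, deadline=None, derandomize=True)
    @given(
        st.lists(st.floats(-100, 100), min_size=4, max_size=8, unique=True),
        st.integers(min_value=2, max_value=6),
    )
    def test_exact_p_matches_enumeration_property(self, pool, n1):
        n1 = min(n1, len(pool) - 2)
        a, b = np.array(pool[:n1]), np.array(pool[n1:])
        res = wilcoxon_rank_sum(a, b)
        assert res.exact
        assert res.p_value == pytest.approx(enum_rank_sum_p(a, b), abs=1e-12)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            wilcoxon_rank_sum([], [1.0])


class TestPearson:
    def test_perfect_linear(self):
        x = np.arange(10.0)
        assert pearson_r(x, 2 * x + 1) == pytest.approx(1.0)
        assert pearson_r(x, -x) == pytest.approx(-1.0)

    def test_pairwise_complete(self):
        x = np.array([1.0, 2.0, np.nan, 4.0, 5.0])
        y = np.array([2.0, 4.0, 100.0, 8.0, 10.0])
        assert pearson_r(x, y) == pytest.approx(1.0)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            pearson_r([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestCohensD:
    def test_equal_means_give_zero_and_symmetric_ci(self):
        g = np.array([1.0, 2.0, 3.0, 4.0])
        res = cohens_d_ci(g, g + 0.0)
        assert res.d == pytest.approx(0.0)
        assert res.ci_low == pytest.approx(-res.ci_high)

    def test_matches_direct_formula_oracle(self):
        rng = np.random.default_rng(12)
        g1 = rng.normal(0.6, 1.1, 14)
        g2 = rng.normal(0.0, 0.9, 9)
        res = cohens_d_ci(g1, g2)
        n1, n2 = len(g1), len(g2)
        sp = np.sqrt(((n1 - 1) * g1.var(ddof=1) + (n2 - 1) * g2.var(ddof=1)) / (n1 + n2 - 2))
        d = (g1.mean() - g2.mean()) / sp
        se = np.sqrt((n1 + n2) / (n1 * n2) + d * d / (2 * (n1 + n2)))
        t = sps.t.ppf(0.975, n1 + n2 - 2)
        assert res.d == pytest.approx(d, abs=1e-10)
        assert res.ci_low == pytest.approx(d - t * se, abs=1e-10)
        assert res.ci_high == pytest.approx(d + t * se, abs=1e-10)

    def test_ci_width_shrinks_with_n(self):
        rng = np.random.default_rng(2)
        base1 = rng.normal(0.5, 1, 4000)
        base2 = rng.normal(0.0, 1, 4000)
        widths = []
        for n in (10, 100, 1000):
            res = cohens_d_ci(base1[:n], base2[:n])
            widths.append(res.ci_high - res.ci_low)
        assert widths[0] > widths[1] > widths[2]

    def test_zero_pooled_variance_rejected(self):
        with pytest.raises(ValueError):
            cohens_d_ci([1.0, 1.0], [1.0, 1.0])


class TestWMWSampleSize:
    def test_antitone_in_effect_size(self):
        ns = [wmw_sample_size(d) for d in (0.2, 0.4, 0.6, 0.9, 1.5)]
        assert all(a >= b for a, b in zip(ns, ns[1:]))

    def test_monotone_in_power(self):
        ns = [wmw_sample_size(0.5, power=p) for p in (0.5, 0.7, 0.8, 0.9, 0.95)]
        assert all(a <= b for a, b in zip(ns, ns[1:]))

    def test_huge_effect_hits_floor(self):
        assert wmw_sample_size(10.0) == 2

    def test_returned_n_achieves_target_power(self):
        for d in (0.35, 0.6, 0.8):
            n = wmw_sample_size(d)
            assert wmw_power(n, d) >= 0.8
            assert wmw_power(n - 1, d) < 0.8

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            wmw_sample_size(0.0)
        with pytest.raises(ValueError):
            wmw_sample_size(0.5, alpha=0.5, power=0.4)
        with pytest.raises(ValueError):
            wmw_sample_size(0.5, parent="cauchy")


class TestBootstrapPrecision:
    def test_constant_masses_rejected(self):
        with pytest.raises(ValueError, match="precision"):
            bootstrap_precision(np.full(10, 5.0))

    def test_recovers_known_variance(self):
        rng = np.random.default_rng(3)
        masses = rng.normal(40.0, 2.0, 50)
        res = bootstrap_precision(masses, B=2000, seed=1)
        assert res.precision == pytest.approx(0.25, rel=0.15)

    def test_converges_across_seeds_at_large_B(self):
        rng = np.random.default_rng(4)
        masses = rng.normal(40.0, 1.5, 19)
        vals = [bootstrap_precision(masses, B=10_000, seed=s).precision for s in range(5)]
        assert (max(vals) - min(vals)) / np.mean(vals) < 0.02

    def test_seed_recorded_and_reproducible(self):
        masses = np.arange(1.0, 20.0)
        a = bootstrap_precision(masses, B=500, seed=42)
        b = bootstrap_precision(masses, B=500, seed=42)
        assert a == b


class TestFidelity:
    def test_paper_scale_percentage(self):
        log = pd.DataFrame({"scheduled": [7] * 30, "confirmed": [7] * 26 + [6] * 4})
        res = fidelity_summary(log)
        assert res.scheduled == 210
        assert res.confirmed == 206
        assert res.pct_confirmed == 98.1

    def test_perfect_log(self):
        log = pd.DataFrame({"scheduled": [7] * 10, "confirmed": [7] * 10})
        res = fidelity_summary(log)
        assert res.pct_confirmed == 100.0
        assert res.deviation_histogram == {0: 10}

    def test_deviation_histogram_counts_days(self):
        log = pd.DataFrame({"scheduled": [7, 7, 7, 7], "confirmed": [7, 6, 6, 5]})
        assert fidelity_summary(log).deviation_histogram == {0: 1, 1: 2, 2: 1}

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            fidelity_summary(pd.DataFrame({"scheduled": [7], "confirmed": [-1]}))

    def test_confirmed_cannot_exceed_scheduled(self):
        with pytest.raises(ValueError):
            fidelity_summary(pd.DataFrame({"scheduled": [7], "confirmed": [8]}))


def test_round_half_up_convention():
    assert round_half_up(98.05, 1) == 98.1
    assert round_half_up(-98.05, 1) == -98.1
    assert round_half_up(22.10526, 1) == 22.1
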