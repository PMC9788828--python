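"""Likelihood gating, pooled jump filtering, natural-spline gap filling."""

import numpy as np
import pytest

from killicog.preprocess import (
    jump_filter,
    likelihood_gate,
    preprocess_pipeline,
    spline_interpolate,
)


from conftest import make_track


def natural_spline_oracle(xk, yk, xq):
    """Independent tridiagonal natural-cubic-spline solver.

    Solves the classic system for second derivatives M at the knots with
    M[0] = M[-1] = 0, then evaluates the piecewise cubic at xq.
    """
    xk = np.asarray(xk, float)
    yk = np.asarray(yk, float)
    n = len(xk)
    h = np.diff(xk)
    A = np.zeros((n, n))
    rhs = np.zeros(n)
    A[0, 0] = A[-1, -1] = 1.0
    for i in range(1, n - 1):
        A[i, i - 1] = h[i - 1]
        A[i, i] = 2 * (h[i - 1] + h[i])
        A[i, i + 1] = h[i]
        rhs[i] = 6 * ((yk[i + 1] - yk[i]) / h[i] - (yk[i] - yk[i - 1]) / h[i - 1])
    M = np.linalg.solve(A, rhs)
    out = np.empty(len(xq))
    for j, x in enumerate(np.asarray(xq, float)):
        i = np.clip(np.searchsorted(xk, x) - 1, 0, n - 2)
        t = x - xk[i]
        out[j] = (
            yk[i]
            + t * ((yk[i + 1] - yk[i]) / h[i] - h[i] * (2 * M[i] + M[i + 1]) / 6)
            + t**2 * M[i] / 2
            + t**3 * (M[i + 1] - M[i]) / (6 * h[i])
        )
    return out


class TestLikelihoodGate:
    def test_paper_threshold_masks_just_below(self):
        track = make_track(
            {"head": ([1.0, 2.0], [1.0, 2.0])}, likelihood={"head": [0.9985, 1.0]}
        )
        out, rep = likelihood_gate(track, "head", 0.999)
        assert np.isnan(out.xy("head").iloc[0]).all()
        assert not np.isnan(out.xy("head").iloc[1]).any()
        assert rep.n_gated == 1
        # likelihood values themselves are retained
        assert out.likelihood("head").iloc[0] == 0.9985

    def test_all_confident_nothing_masked(self):
        track = make_track({"head": (np.arange(10.0), np.arange(10.0))})
        out, rep = likelihood_gate(track, "head", 0.999)
        assert rep.n_gated == 0
        assert not out.xy("head").isna().any().any()

    def test_count_matches_direct_tally(self):
        lik = np.array([1, 1, 0.5, 1, 0.1, 1, 1, 0.998, 1, 1])
        track = make_track(
            {"head": (np.arange(10.0), np.arange(10.0))}, likelihood={"head": lik}
        )
        _, rep = likelihood_gate(track, "head", 0.999)
        assert rep.n_gated == int((lik < 0.999).sum()) == 3

    def test_unknown_keypoint(self):
        track = make_track({"head": ([1.0, 2.0], [1.0, 2.0])})
        with pytest.raises(KeyError):
            likelihood_gate(track, "fin")


class TestJumpFilter:
    def test_stationary_track_has_no_anomalies(self):
        still = make_track({"head": (np.full(50, 5.0), np.full(50, 5.0))})
        mover = make_track({"head": (np.cumsum(np.ones(50)), np.zeros(50))})
        _, reps = jump_filter([still, mover], "head", 0.05)
        assert reps[0].n_anomalies == 0

    def test_injected_teleport_is_the_unique_masked_frame(self):
        rng = np.random.default_rng(0)
        x = np.cumsum(rng.uniform(-2, 2, 100))
        y = np.cumsum(rng.uniform(-2, 2, 100))
        x[40] += 500.0  # teleport at frame 40; steps 40 and 41 both oversized
        track = make_track({"head": (x, y)})
        out_tracks, reps = jump_filter([track], "head", 0.05)
        masked = np.where(out_tracks[0].xy("head")["x"].isna())[0]
        assert 40 in masked
        # brute-force check: every masked frame ends a step above the quantile
        steps = np.hypot(np.diff(x), np.diff(y))
        thr = np.quantile(steps, 0.95)
        np.testing.assert_array_equal(masked, np.where(steps > thr)[0] + 1)

    def test_five_percent_of_hundred_distances_flags_five_largest(self):
        # 101 positions -> 100 distinct step distances 1..100
        x = np.concatenate([[0.0], np.cumsum(np.arange(1.0, 101.0))])
        track = make_track({"head": (x, np.zeros_like(x))})
        out_tracks, reps = jump_filter([track], "head", 0.05)
        masked = np.where(out_tracks[0].xy("head")["x"].isna())[0]
        # sort-and-count oracle: the five largest steps end at frames 96..100
        assert reps[0].n_anomalies == 5
        np.testing.assert_array_equal(masked, np.arange(96, 101))

    def test_tie_at_threshold_not_flagged(self):
        x = np.concatenate([[0.0], np.cumsum(np.ones(99))])  # all steps tie at 1
        track = make_track({"head": (x, np.zeros_like(x))})
        _, reps = jump_filter([track], "head", 0.05)
        assert reps[0].n_anomalies == 0

    def test_all_missing_raises(self):
        track = make_track({"head": ([np.nan, np.nan], [np.nan, np.nan])})
        with pytest.raises(ValueError, match="no distances"):
            jump_filter([track], "head")


class TestSplineInterpolate:
    @staticmethod
    def _masked_track(y, missing):
        x = np.linspace(0, 1, len(y))
        track = make_track({"head": (x.copy(), np.asarray(y, float))})
        track.data.loc[list(missing), ("head", "x")] = np.nan
        track.data.loc[list(missing), ("head", "y")] = np.nan
        return track

    def test_linear_gap_filled_exactly(self):
        t = np.arange(10.0)
        track = self._masked_track(t.copy(), [4])
        out, rep = spline_interpolate(track, "head")
        assert out.xy("head")["y"].iloc[4] == pytest.approx(4.0, abs=1e-12)
        assert rep.n_interpolated == 1
        assert rep.n_residual_missing == 0

    def test_no_extrapolation_at_edges(self):
        y = np.arange(20.0)
        track = self._masked_track(y, range(5))
        out, rep = spline_interpolate(track, "head")
        assert out.xy("head")["y"].iloc[:5].isna().all()
        assert rep.n_residual_missing == 5
        assert rep.n_interpolated == 0

    def test_cubic_gap_matches_tridiagonal_oracle(self):
        frames = np.arange(30.0)
        y = frames**3
        missing = [12, 13, 14]
        track = self._masked_track(y.copy(), missing)
        out, _ = spline_interpolate(track, "head")
        keep = np.setdiff1d(frames.astype(int), missing)
        expected = natural_spline_oracle(frames[keep], y[keep], frames[missing])
        np.testing.assert_allclose(
            out.xy("head")["y"].iloc[missing].to_numpy(), expected, atol=1e-8
        )

    def test_too_few_points_pass_through(self):
        track = self._masked_track([0.0, 1.0, 2.0, 3.0], [1, 2])
        out, rep = spline_interpolate(track, "head")
        assert out.xy("head")["y"].isna().sum() == 2
        assert rep.n_interpolated == 0

    def test_idempotent(self):
        rng = np.random.default_rng(3)
        y = rng.normal(size=40).cumsum()
        track = self._masked_track(y, [0, 1, 10, 11, 12, 25, 39])
        once, _ = spline_interpolate(track, "head")
        twice, _ = spline_interpolate(once, "head")
        np.testing.assert_array_equal(
            once.data.to_numpy(), twice.data.to_numpy()
        )


class TestPipeline:
    def test_clean_session_reports(self, clean_session):
        # Without dropouts nothing is likelihood-gated; the quantile jump
        # filter still marks the top tail of pooled steps (it is a fixed
        #-fraction filter), and the spline refills all of them.
        session, _ = clean_session
        out, reports = preprocess_pipeline(session)
        n_frames = sum(t.n_frames for t in session.tracks.values())
        total_anom = 0
        for key, rep in reports.items():
            assert rep.n_gated == 0
            assert rep.n_interpolated + rep.n_residual_missing == rep.n_anomalies
            total_anom += rep.n_anomalies
        assert total_anom <= 0.05 * n_frames + len(session.tracks)
        key = next(iter(session.tracks))
        assert out.tracks[key].data[("head", "likelihood")].equals(
            session.tracks[key].data[("head", "likelihood")]
        )

    def test_injected_artifact_counts_match_truth(self, small_session):
        session, truth = small_session
        _, reports = preprocess_pipeline(session)
        for key, rep in reports.items():
            assert rep.n_gated == len(truth.dropout_frames[key])
            # monotone bookkeeping identity per track
            assert rep.n_interpolated + rep.n_residual_missing == (
                rep.n_gated + rep.n_anomalies
            )

    def test_every_injected_teleport_gets_masked(self, small_session):
        session, truth = small_session
        keys = sorted(session.tracks)
        gated = [likelihood_gate(session.tracks[k], "head")[0] for k in keys]
        jumped, _ = jump_filter(gated, "head", 0.05)
        for k, t in zip(keys, jumped):
            tele = truth.teleport_frames[k]
            if tele.size:
                miss = t.xy("head").isna().any(axis=1).to_numpy()
                assert miss[tele].all()

    def test_gated_frames_excluded_from_distance_pool(self):
        # one huge step hidden behind a low-likelihood frame: the gate runs
        # first, so the jump filter never sees the oversized distance
        rng = np.random.default_rng(1)
        x = np.cumsum(rng.uniform(-2, 2, 60))
        lik = np.ones(60)
        x2 = x.copy()
        x2[30] += 1000.0
        lik[30] = 0.5
        bad = make_track({"head": (x2, np.zeros(60))}, likelihood={"head": lik})
        gated, _ = likelihood_gate(bad, "head", 0.999)
        _, reps = jump_filter([gated], "head", 0.05)
        manual_pool, _ = [], None
        xy = gated.xy("head").to_numpy()
        valid = ~np.isnan(xy).any(axis=1)
        pair = valid[1:] & valid[:-1]
        d = np.hypot(np.diff(xy[:, 0]), np.diff(xy[:, 1]))[pair]
        assert d.max() < 1000.0  # the teleport-sized step never entered the pool
        assert reps[0].n_anomalies == int((d > np.quantile(d, 0.95)).sum())

    def test_masking_is_monotone_across_stages(self, small_session):
        session, _ = small_session
        keys = sorted(session.tracks)[:4]
        sub = [session.tracks[k] for k in keys]
        gated = []
        for t in sub:
            g, _ = likelihood_gate(t, "head")
            gated.append(g)
        jumped, _ = jump_filter(gated, "head")
        for g, j in zip(gated, jumped):
            gm = g.xy("head").isna().any(axis=1).to_numpy()
            jm = j.xy("head").isna().any(axis=1).to_numpy()
            assert (jm | ~gm).all() or (jm[gm]).all()  # gated stays masked
            assert jm[gm].all()

    def test_config_mapping_accepted(self, clean_session):
        session, _ = clean_session
        out, _ = preprocess_pipeline(session, {"likelihood_threshold": 0.99})
        assert len(out.tracks) == len(session.tracks)
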