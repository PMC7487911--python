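"""Rank p-values, robust correlation (FAST-MCD), the composite score and its
normal calibration / FDR control."""

import math

import numpy as np
import pytest

from dcmscan.composite import (
    CorrMatrix,
    DegenerateStatisticsError,
    PMatrix,
    bh_qvalues,
    build_pmatrix,
    dcms_scores,
    fast_mcd,
    huber_normal_fit,
    mcd_correlation,
    normal_pvalues,
    rank_pvalues,
)
from dcmscan.popstats import StatTrack

from oracles import bh_oracle, exhaustive_mcd_oracle, rank_pvalue_oracle


class TestRankPvalues:
    def test_single_value_is_half(self):
        assert rank_pvalues(np.array([3.0]), "left")[0] == 0.5
        assert rank_pvalues(np.array([3.0]), "right")[0] == 0.5

    def test_forced_arithmetic(self):
        got = rank_pvalues(np.array([1.0, 2.0, 3.0]), "right")
        assert np.allclose(got, [0.75, 0.5, 0.25])

    def test_ties_match_enumeration_oracle(self, rng):
        for _ in range(30):
            vals = rng.integers(0, 5, size=rng.integers(2, 40)).astype(float)
            for tail in ("left", "right"):
                got = rank_pvalues(vals, tail)
                assert np.allclose(got, rank_pvalue_oracle(vals.tolist(), tail))
                assert np.all((got > 0) & (got < 1))

    def test_monotone_transform_invariance(self, rng):
        vals = rng.normal(size=200)
        p1 = rank_pvalues(vals, "right")
        p2 = rank_pvalues(np.exp(vals), "right")  # strictly increasing map
        assert np.allclose(p1, p2)

    def test_contract_errors(self):
        with pytest.raises(ValueError, match="empty"):
            rank_pvalues(np.array([]), "left")
        with pytest.raises(ValueError, match="tail"):
            rank_pvalues(np.array([1.0]), "both")


class TestDcmsScores:
    def _pmat(self, p):
        P = np.atleast_2d(p)
        return PMatrix(P, ["a", "b", "c"])

    def test_neutral_pvalues_give_zero(self):
        R = CorrMatrix(np.eye(3), ["a", "b", "c"])
        assert dcms_scores(self._pmat([0.5, 0.5, 0.5]), R)[0] == pytest.approx(0.0)

    def test_uncorrelated_case_is_sum_of_logits(self):
        R = CorrMatrix(np.eye(3), ["a", "b", "c"])
        got = dcms_scores(self._pmat([0.1, 0.1, 0.1]), R)[0]
        assert got == pytest.approx(3 * math.log(9), rel=1e-12)

    def test_fully_correlated_case_is_average(self):
        R = CorrMatrix(np.ones((3, 3)), ["a", "b", "c"])
        got = dcms_scores(self._pmat([0.1, 0.1, 0.1]), R)[0]
        assert got == pytest.approx(math.log(9), rel=1e-12)

    def test_strictly_decreasing_in_each_pvalue(self, rng):
        R = CorrMatrix(np.eye(3) * 0.4 + 0.6, ["a", "b", "c"])
        base = np.array([0.3, 0.6, 0.2])
        s0 = dcms_scores(self._pmat(base), R)[0]
        for t in range(3):
            bumped = base.copy()
            bumped[t] += 0.05
            assert dcms_scores(self._pmat(bumped), R)[0] < s0

    def test_out_of_range_p_rejected(self):
        with pytest.raises(ValueError):
            PMatrix(np.array([[0.0, 0.5, 0.5]]), ["a", "b", "c"])

    def test_log_base_rescales(self):
        R = CorrMatrix(np.eye(3), ["a", "b", "c"])
        nat = dcms_scores(self._pmat([0.1, 0.2, 0.3]), R)
        b10 = dcms_scores(self._pmat([0.1, 0.2, 0.3]), R, log_base=10.0)
        assert np.allclose(b10, nat / math.log(10))


class TestCorrMatrix:
    def test_weight_factor_bounds(self, rng):
        for _ in range(20):
            A = rng.normal(size=(4, 4))
            R = np.corrcoef(A @ A.T)  # a valid correlation matrix
            cm = CorrMatrix(R, list("wxyz"))
            w = cm.weights()
            assert np.all(w >= 1.0) and np.all(w <= 4.0)

    def test_invalid_matrices_rejected(self):
        with pytest.raises(ValueError, match="symmetric"):
            CorrMatrix(np.array([[1.0, 0.2], [0.4, 1.0]]), ["a", "b"])
        with pytest.raises(ValueError, match="unit diagonal"):
            CorrMatrix(np.array([[2.0, 0.0], [0.0, 1.0]]), ["a", "b"])


class TestMcd:
    def test_identical_columns_have_unit_correlation(self, rng):
        x = rng.normal(size=400)
        y = rng.normal(size=400)
        S = np.column_stack([x, x, y])
        R = mcd_correlation(S, nsamp=300, seed=1)
        assert R.R[0, 1] == pytest.approx(1.0)
        assert abs(R.R[0, 2]) < 0.2

    def test_independent_columns_near_zero(self, rng):
        S = rng.normal(size=(5000, 3))
        R = mcd_correlation(S, nsamp=200, seed=2)
        off = R.R[~np.eye(3, dtype=bool)]
        assert np.all(np.abs(off) < 0.1)

    def test_tiny_sample_equals_exhaustive_oracle(self, rng):
        for trial in range(5):
            X = rng.normal(size=(12, 2))
            h = 9
            mu, cov, support = fast_mcd(X, nsamp=10**6, seed=3, h=h, reweight=False)
            omu, ocov, odet = exhaustive_mcd_oracle(X, h)
            assert np.allclose(mu, omu)
            # implementation applies the consistency factor; compare shapes
            assert np.allclose(cov / cov[0, 0], ocov / ocov[0, 0])

    def test_constant_column_rejected(self, rng):
        S = np.column_stack([np.ones(50), rng.normal(size=50)])
        with pytest.raises(DegenerateStatisticsError, match="zero spread"):
            mcd_correlation(S, seed=0)

    def test_contaminated_correlation_recovered(self, rng):
        # strong outlier cluster flips the classical correlation sign
        n = 800
        z = rng.normal(size=n)
        S = np.column_stack([z, z + rng.normal(0, 0.4, n)])
        out = rng.normal(size=(120, 2)) * [1.5, 1.5] @ np.array([[1, -1], [-1, 1.0]])
        Sc = np.vstack([S, out + [4, -4]])
        R = mcd_correlation(Sc, nsamp=300, seed=4)
        assert R.R[0, 1] > 0.7
        try:
            from sklearn.covariance import MinCovDet

            skl = MinCovDet(support_fraction=0.75, random_state=0).fit(Sc)
            c = skl.covariance_
            r_skl = c[0, 1] / np.sqrt(c[0, 0] * c[1, 1])
            assert R.R[0, 1] == pytest.approx(r_skl, abs=0.15)
        except ImportError:
            pass

    def test_reproducible_for_fixed_seed(self, rng):
        S = rng.normal(size=(300, 3))
        R1 = mcd_correlation(S, nsamp=50, seed=9)
        R2 = mcd_correlation(S, nsamp=50, seed=9)
        assert np.array_equal(R1.R, R2.R)


class TestHuberFit:
    def test_equals_mean_without_outliers(self, rng):
        # U-shaped symmetric sample: every |residual| < k * scale, so all
        # Huber weights are 1 and the estimate converges to the mean
        x = np.cos(rng.uniform(0, np.pi, 500))
        mu, sd = huber_normal_fit(x)
        assert mu == pytest.approx(np.mean(x), abs=1e-6)
        assert sd > 0

    def test_resists_gross_contamination(self, rng):
        clean = rng.normal(0.0, 1.0, 950)
        x = np.concatenate([clean, np.full(50, 40.0)])
        mu, sd = huber_normal_fit(x)
        ref = np.median(clean)
        assert abs(mu - ref) < abs(np.mean(x) - ref)
        assert sd < 2.0

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError, match="degenerate|spread"):
            huber_normal_fit(np.full(50, 3.0))

    def test_matches_statsmodels_rlm(self, rng):
        import statsmodels.api as sm

        x = rng.standard_t(df=3, size=400)
        mu, sd = huber_normal_fit(x)
        fit = sm.RLM(x, np.ones((x.size, 1)), M=sm.robust.norms.HuberT()).fit(
            scale_est="mad", update_scale=True
        )
        assert mu == pytest.approx(float(fit.params[0]), abs=5e-3)
        assert sd == pytest.approx(float(fit.scale), rel=0.05)


class TestNormalPvalues:
    def test_reference_quantiles(self):
        p = normal_pvalues(np.array([0.0, 1.959964]), mu=0.0, sd=1.0)
        assert p[0] == pytest.approx(0.5)
        assert p[1] == pytest.approx(0.025, rel=1e-4)

    def test_order_preserving(self, rng):
        x = rng.normal(size=50)
        p = normal_pvalues(x, 0.0, 2.0)
        assert np.all(np.diff(p[np.argsort(x)]) <= 0)

    def test_nonpositive_sd_rejected(self):
        with pytest.raises(ValueError):
            normal_pvalues(np.array([1.0]), 0.0, 0.0)


class TestBhQvalues:
    def test_single_p_unchanged(self):
        assert bh_qvalues(np.array([0.031]))[0] == pytest.approx(0.031)

    def test_forced_arithmetic(self):
        got = bh_qvalues(np.array([0.01, 0.02, 0.03, 0.04]))
        assert np.allclose(got, 0.04)

    def test_matches_step_up_oracle(self, rng):
        for _ in range(30):
            p = rng.random(rng.integers(1, 50))
            assert np.allclose(bh_qvalues(p), bh_oracle(p.tolist()))

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_qvalues(np.array([0.5, 1.2]))


def test_build_pmatrix_tail_directions(rng):
    vals = rng.normal(size=60)
    tracks = [
        StatTrack("FST", "A", vals),
        StatTrack("PI", "A", vals),
    ]
    P = build_pmatrix(tracks)
    # same values, opposite tails: p_right + p_left = 1 (no ties here)
    assert np.allclose(P.P[:, 0] + P.P[:, 1], 1.0)
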