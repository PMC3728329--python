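"""Moderated linear models: group means, variance squeezing, moderated
t/F tests, the overall-F gate, and BH adjustment."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import radresponse as rr
from radresponse.diffexpr import CONTRASTS, _trigamma_inverse
from radresponse.errors import DataError, DesignError, ParameterError

from conftest import five_group_design, make_matrix


def bh_oracle(p):
    """Literal step-up definition of the BH adjusted p-values."""
    p = np.asarray(p, dtype=float)
    n = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(n)
    prev = 1.0
    for i in range(n - 1, -1, -1):
        val = min(prev, p[order[i]] * n / (i + 1))
        adj[order[i]] = val
        prev = val
    return adj


def naive_group_fit(values, groups):
    """Brute-force per-row group means and pooled residual variance."""
    labels = sorted(set(groups))
    means = {}
    rss = np.zeros(values.shape[0])
    for g in labels:
        cols = [j for j, lab in enumerate(groups) if lab == g]
        means[g] = values[:, cols].mean(axis=1)
        rss += ((values[:, cols] - means[g][:, None]) ** 2).sum(axis=1)
    df = values.shape[1] - len(labels)
    return means, rss / df, df


class TestFitGroupMeans:
    def test_identical_replicates_zero_variance(self):
        design = five_group_design(n_reps=3)
        row = np.repeat([1.0, 2.0, 3.0, 4.0, 5.0], 3)
        m = make_matrix(row[None, :])
        m.data.columns = design.samples
        fit = rr.fit_group_means(m, design)
        assert fit.s2.iloc[0] == 0.0
        np.testing.assert_allclose(fit.means.iloc[0], [1, 2, 3, 4, 5])

    def test_matches_naive_oracle(self, rng):
        design = five_group_design(n_reps=3)
        values = rng.normal(size=(40, 15))
        m = make_matrix(values)
        m.data.columns = design.samples
        fit = rr.fit_group_means(m, design)
        groups = [s[0] for s in design.samples]
        means, s2, df = naive_group_fit(values, groups)
        assert fit.df_residual == df == 10
        for g in "ABCDE":
            np.testing.assert_allclose(fit.means[g], means[g], atol=1e-12)
        np.testing.assert_allclose(fit.s2, s2, atol=1e-12)

    def test_time_contrast_recovers_planted_effect(self, small_sim, small_fit):
        _, _, _, truth = small_sim
        true_time = truth.contrast_effects()["TIME"]
        common = small_fit.coefficients.index
        err = small_fit.coefficients["TIME"] - true_time.loc[common]
        # replicate-averaged contrast noise: sd = sqrt(s2 * sum(c^2/n))
        assert np.abs(err.mean()) < 0.02
        assert err.std() < 0.25

    def test_missing_group_raises(self):
        design = rr.SampleDesign.from_groups({"a1": "A", "a2": "A", "b1": "B", "b2": "B"})
        m = make_matrix(np.random.default_rng(0).normal(size=(12, 4)))
        m.data.columns = design.samples
        fit = rr.fit_group_means(m, design)
        with pytest.raises(DesignError):
            rr.moderated_tests(fit, contrasts={"TIME": CONTRASTS["TIME"]})


class TestSqueezeVariances:
    def test_parameter_recovery_direct(self):
        rng = np.random.default_rng(7)
        d0, s0sq, df, n = 4.0, 0.05, 10, 5000
        sigma2 = s0sq * d0 / rng.chisquare(d0, n)
        s2 = sigma2 * rng.chisquare(df, n) / df
        d0_hat, s0sq_hat, s2_post = rr.squeeze_variances(pd.Series(s2), df)
        assert 0.5 * d0 <= d0_hat <= 1.5 * d0
        assert 0.75 * s0sq <= s0sq_hat <= 1.25 * s0sq
        # posterior between the observed variance and the prior, rowwise
        lo = np.minimum(s2, s0sq_hat)
        hi = np.maximum(s2, s0sq_hat)
        assert ((s2_post >= lo - 1e-12) & (s2_post <= hi + 1e-12)).all()

    def test_equal_variances_infinite_prior(self):
        from scipy.special import digamma

        s2 = pd.Series(np.full(100, 0.3))
        d0, s0sq, s2_post = rr.squeeze_variances(s2, 10)
        assert np.isinf(d0)
        # the moment equations back out the chi2 log-bias of the common
        # value: s0^2 = s^2 * exp(log(df/2) - digamma(df/2)) -> s^2 as df grows
        assert s0sq == pytest.approx(0.3 * np.exp(np.log(5.0) - digamma(5.0)))
        assert s0sq == pytest.approx(0.3, rel=0.15)
        np.testing.assert_allclose(s2_post, s0sq)

    def test_all_zero_variances_rejected(self):
        with pytest.raises(DataError):
            rr.squeeze_variances(pd.Series(np.zeros(100)), 10)

    def test_zero_rows_excluded_but_squeezed(self):
        rng = np.random.default_rng(3)
        s2 = rng.chisquare(5, 200) / 5 * 0.1
        s2[:5] = 0.0
        d0, s0sq, s2_post = rr.squeeze_variances(pd.Series(s2), 10)
        assert np.isfinite(d0) and d0 > 0 and s0sq > 0
        # zero-variance rows are shrunk toward the prior, not left at zero
        expected = d0 * s0sq / (d0 + 10)
        np.testing.assert_allclose(s2_post[:5], expected)

    def test_trigamma_inverse_roundtrip(self):
        from scipy.special import polygamma
        for x in (0.05, 0.5, 2.0, 25.0, 400.0):
            y = float(polygamma(1, x))
            assert _trigamma_inverse(y) == pytest.approx(x, rel=1e-6)


class TestModeratedTests:
    def _simple_fit(self, rng, n=30):
        design = five_group_design(3)
        values = rng.normal(size=(n, 15))
        m = make_matrix(values)
        m.data.columns = design.samples
        return rr.fit_group_means(m, design), values

    def test_d0_zero_reproduces_ordinary_t(self, rng):
        fit, values = self._simple_fit(rng)
        mfit = rr.moderated_tests(fit, d0=0.0)
        # textbook computation for LT_vs_CTRL on the first row
        row = values[0]
        mA, mB, mC = row[0:3].mean(), row[3:6].mean(), row[6:9].mean()
        groups = row.reshape(5, 3)
        s2 = ((groups - groups.mean(axis=1, keepdims=True)) ** 2).sum() / 10
        beta = (mB + mC) / 2 - mA
        t_ref = beta / np.sqrt(s2 * (1.0 + 0.25 + 0.25) / 3)
        assert mfit.t["LT_vs_CTRL"].iloc[0] == pytest.approx(t_ref, rel=1e-10)
        p_ref = 2 * stats.t.sf(abs(t_ref), 10)
        assert mfit.p["LT_vs_CTRL"].iloc[0] == pytest.approx(p_ref, rel=1e-10)

    def test_d0_infinite_pooled_limit(self, rng):
        fit, _ = self._simple_fit(rng, n=200)
        mfit = rr.moderated_tests(fit, d0=np.inf, s0sq=1.0)
        np.testing.assert_allclose(mfit.prior.s2_post, 1.0)
        # t reduces to beta / sqrt(s0^2 v_c), normal reference
        beta = mfit.coefficients["TIME"]
        t_ref = beta / np.sqrt(1.0 * 1.0 / 3.0)
        np.testing.assert_allclose(mfit.t["TIME"], t_ref, rtol=1e-12)
        np.testing.assert_allclose(
            mfit.p["TIME"], 2 * stats.norm.sf(np.abs(t_ref)), rtol=1e-10
        )

    def test_moderated_interpolates_between_limits(self, rng):
        fit, _ = self._simple_fit(rng, n=100)
        m0 = rr.moderated_tests(fit, d0=0.0)
        minf = rr.moderated_tests(fit, d0=np.inf)
        mmid = rr.moderated_tests(fit, d0=4.0)
        lo = np.minimum(m0.prior.s2_post, minf.prior.s2_post)
        hi = np.maximum(m0.prior.s2_post, minf.prior.s2_post)
        assert ((mmid.prior.s2_post >= lo - 1e-12) & (mmid.prior.s2_post <= hi + 1e-12)).all()

    def test_zero_beta_gives_t_zero_p_one(self):
        design = five_group_design(2)
        rng = np.random.default_rng(5)
        noise = rng.normal(size=(20, 10)) * 0.1
        # symmetrize so every group mean is exactly equal
        values = noise - np.repeat(noise.reshape(20, 5, 2).mean(axis=2), 2, axis=1)
        m = make_matrix(values + 5.0)
        m.data.columns = design.samples
        mfit = rr.moderated_tests(rr.fit_group_means(m, design), d0=0.0)
        np.testing.assert_allclose(mfit.coefficients["TIME"], 0.0, atol=1e-12)
        np.testing.assert_allclose(mfit.t["TIME"], 0.0, atol=1e-12)
        np.testing.assert_allclose(mfit.p["TIME"], 1.0)

    def test_contrasts_sum_to_zero_and_shift_invariance(self, rng):
        fit, values = self._simple_fit(rng)
        for name, c in CONTRASTS.items():
            assert abs(c.sum()) < 1e-12
        design = five_group_design(3)
        shifted = make_matrix(values + 3.7)
        shifted.data.columns = design.samples
        mfit1 = rr.moderated_tests(fit, d0=1.0, s0sq=0.5)
        mfit2 = rr.moderated_tests(rr.fit_group_means(shifted, design), d0=1.0, s0sq=0.5)
        pd.testing.assert_frame_equal(mfit1.coefficients, mfit2.coefficients,
                                      check_exact=False, atol=1e-10)

    def test_gate_modes_and_bad_q(self, small_fit, small_sim):
        _, matrix, design, _ = small_sim
        filtered, _ = rr.iqr_filter(matrix)
        fit = rr.fit_group_means(filtered, design)
        with pytest.raises(ParameterError):
            rr.moderated_tests(fit, q=1.5)
        mfit_c = rr.moderated_tests(fit, gate="contrasts")
        assert mfit_c.F_df1 == 3
        assert small_fit.F_df1 == 4

    def test_sensitivity_and_fdp_on_planted_time_effects(self, small_sim, small_fit):
        _, _, _, truth = small_sim
        true_time = truth.contrast_effects()["TIME"]
        idx = small_fit.coefficients.index
        sig = (small_fit.p_adj["TIME"] < 0.05) & small_fit.gate
        strong = idx[np.abs(true_time.loc[idx]) >= 1.0]
        sensitivity = sig.loc[strong].mean()
        assert sensitivity >= 0.8
        null_rows = idx[true_time.loc[idx] == 0.0]
        false_calls = sig.loc[null_rows].sum()
        fdp = false_calls / max(int(sig.sum()), 1)
        assert fdp <= 0.10


class TestBhAdjust:
    def test_hand_example(self):
        np.testing.assert_allclose(
            rr.bh_adjust([0.01, 0.02, 0.03, 0.8]), [0.04, 0.04, 0.04, 0.8]
        )

    def test_single_and_equal(self):
        assert rr.bh_adjust([0.3]) == pytest.approx([0.3])
        np.testing.assert_allclose(rr.bh_adjust([0.2, 0.2, 0.2]), 0.2)

    def test_matches_oracle_random_vectors(self, rng):
        for _ in range(300):
            p = rng.uniform(size=int(rng.integers(1, 40)))
            np.testing.assert_allclose(rr.bh_adjust(p), bh_oracle(p), atol=1e-12)

    def test_monotone_and_bounded(self, rng):
        p = rng.uniform(size=500)
        adj = rr.bh_adjust(p)
        assert (adj >= p - 1e-15).all() and (adj <= 1.0 + 1e-15).all()
        order = np.argsort(p)
        assert (np.diff(adj[order]) >= -1e-12).all()

    def test_invalid_p_rejected(self):
        with pytest.raises(ParameterError):
            rr.bh_adjust([0.5, 1.2])
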