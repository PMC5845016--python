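"""Moderated t-test: oracle equivalence, calibration, shrinkage properties."""

import numpy as np
import pandas as pd
import pytest
from scipy import special

from uvphos import bh_adjust, fit_ebayes, moderated_one_sample_test
from uvphos.ebayes import VAR_FLOOR, trigamma_inverse

from conftest import EBAYES_FIXTURE, LIMMA_REFERENCE


def bisection_hyperparameters(s2, df, tol=1e-10):
    """Independent solver of the two log-variance moment equations.

    Same model as the implementation under test but solved by plain
    bisection on trigamma(d0/2) = excess variance of log s2.
    """
    s2 = np.maximum(np.asarray(s2, float), VAR_FLOOR)
    df = np.asarray(df, float)
    e = np.log(s2) - special.digamma(df / 2) + np.log(df / 2)
    emean = e.mean()
    evar = e.var(ddof=1) - np.mean(special.polygamma(1, df / 2))
    if evar <= 0:
        return np.inf, float(np.exp(emean))
    lo, hi = 1e-8, 1e10
    while hi - lo > tol * max(1.0, lo):
        mid = 0.5 * (lo + hi)
        if special.polygamma(1, mid / 2) - evar > 0:
            lo = mid  # trigamma too large -> d0 too small
        else:
            hi = mid
    d0 = 0.5 * (lo + hi)
    s02 = float(np.exp(emean + special.digamma(d0 / 2) - np.log(d0 / 2)))
    return d0, s02


class TestHyperparameterFit:
    def test_matches_limma_on_frozen_fixture(self):
        fit = fit_ebayes(EBAYES_FIXTURE)
        assert fit.d0 == pytest.approx(LIMMA_REFERENCE["d0"], abs=1e-9)
        assert fit.s02 == pytest.approx(LIMMA_REFERENCE["s02"], abs=1e-12)
        np.testing.assert_allclose(fit.t_mod, LIMMA_REFERENCE["t"], atol=1e-9)
        np.testing.assert_allclose(fit.p, LIMMA_REFERENCE["p"], atol=1e-10)

    @pytest.mark.parametrize("seed,n_features", [(0, 6), (1, 50), (2, 200)])
    def test_matches_bisection_oracle(self, seed, n_features):
        rng = np.random.default_rng(seed)
        sds = rng.uniform(0.1, 1.0, size=n_features)
        X = rng.normal(0, 1, size=(n_features, 3)) * sds[:, None]
        fit = fit_ebayes(X)
        d0_ref, s02_ref = bisection_hyperparameters(fit.s2, fit.df)
        if np.isinf(d0_ref):
            assert np.isinf(fit.d0)
        else:
            assert fit.d0 == pytest.approx(d0_ref, abs=1e-6)
        assert fit.s02 == pytest.approx(s02_ref, abs=1e-6)
        # t from the oracle hyperparameters
        s2t = (d0_ref * s02_ref + fit.df * fit.s2) / (d0_ref + fit.df)
        t_ref = fit.mean_log2 / np.sqrt(s2t / fit.n_obs)
        np.testing.assert_allclose(fit.t_mod, t_ref, atol=1e-6)

    def test_homogeneous_variances_give_infinite_prior_df(self):
        # identical s2 across features -> no excess heterogeneity
        X = np.array([[0.0, 1.0, 2.0], [1.0, 2.0, 3.0], [-1.0, 0.0, 1.0], [2.0, 3.0, 4.0]])
        fit = fit_ebayes(X)
        assert np.isinf(fit.d0)
        np.testing.assert_allclose(fit.s2_tilde, fit.s02)
        # t equals the z-like statistic mean / sqrt(s02 / n)
        np.testing.assert_allclose(fit.t_mod, fit.mean_log2 / np.sqrt(fit.s02 / 3))

    def test_d0_zero_override_recovers_ordinary_t(self):
        rng = np.random.default_rng(3)
        X = rng.normal(0, 1, size=(30, 4)) * rng.uniform(0.2, 2, size=(30, 1))
        fit = fit_ebayes(X, d0_override=0.0)
        t_ordinary = X.mean(axis=1) / np.sqrt(X.var(axis=1, ddof=1) / 4)
        np.testing.assert_allclose(fit.t_mod, t_ordinary, atol=1e-10)

    def test_all_zero_variances_error(self):
        X = np.tile([[1.0, 1.0, 1.0]], (5, 1))
        with pytest.raises(ValueError, match="variance"):
            fit_ebayes(X)

    def test_single_replicate_features_flagged_not_tested(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(10, 3))
        X[0, 1:] = np.nan  # one feature with a single observation
        fit = fit_ebayes(X)
        assert fit.df[0] == 0
        assert np.isnan(fit.t_mod[0]) and np.isnan(fit.p[0])
        assert fit.s2_tilde[0] == pytest.approx(fit.s02)
        assert fit.df_total[0] == pytest.approx(fit.d0)


class TestShrinkageProperties:
    def test_posterior_variance_between_prior_and_sample(self):
        rng = np.random.default_rng(5)
        X = rng.normal(0, 1, size=(100, 3)) * rng.uniform(0.05, 3, size=(100, 1))
        fit = fit_ebayes(X)
        lo = np.minimum(fit.s2, fit.s02)
        hi = np.maximum(fit.s2, fit.s02)
        ok = fit.df > 0
        assert np.all(fit.s2_tilde[ok] >= lo[ok] - 1e-12)
        assert np.all(fit.s2_tilde[ok] <= hi[ok] + 1e-12)

    def test_t_magnitude_monotone_in_sample_variance(self):
        # same mean, increasing s2 -> |t_mod| non-increasing
        base = np.array([[0.9, 1.1], [0.5, 1.5], [0.0, 2.0], [-0.5, 2.5], [1.0, 1.0 + 1e-4]])
        fit = fit_ebayes(base)
        order = np.argsort(fit.s2)
        t_sorted = np.abs(fit.t_mod[order])
        assert np.all(np.diff(t_sorted) <= 1e-12)

    def test_trigamma_inverse_roundtrip(self):
        for x in [1e-6, 0.01, 0.5, 2.0, 50.0]:
            y = trigamma_inverse(x)
            assert special.polygamma(1, y) == pytest.approx(x, rel=1e-9)


class TestModeratedTest:
    def test_zero_mean_gives_t_zero_p_one(self):
        X = np.array([[1.0, -1.0], [0.5, -0.5], [2.0, -2.0], [0.2, 0.4]])
        fit = fit_ebayes(X)
        res = moderated_one_sample_test(fit)
        assert res["t_mod"].iloc[0] == pytest.approx(0.0)
        assert res["p"].iloc[0] == pytest.approx(1.0)

    def test_null_type_i_error_within_binomial_ci(self, null_matrix):
        fit = fit_ebayes(null_matrix)
        frac = float(np.mean(fit.p < 0.01))
        half = 2.576 * np.sqrt(0.01 * 0.99 / 10_000)
        assert 0.01 - half <= frac <= 0.01 + half

    def test_shrinkage_beats_ordinary_t_power_at_two_replicates(self):
        rng = np.random.default_rng(11)
        n = 4000
        effect = np.zeros(n)
        effect[:400] = 1.5
        X = effect[:, None] + rng.normal(0, 0.35, size=(n, 2))
        fit = fit_ebayes(X)
        power_mod = float(np.mean(fit.p[:400] < 0.01))
        from scipy import stats

        t_ord = X.mean(axis=1) / np.sqrt(X.var(axis=1, ddof=1) / 2)
        p_ord = 2 * stats.t.sf(np.abs(t_ord), 1)
        power_ord = float(np.mean(p_ord[:400] < 0.01))
        assert power_mod > power_ord
        assert power_mod > 0.9  # near-certain detection at 1.5 / 0.35

    def test_missing_contrast_raises(self, phospho_sim):
        _, table, _ = phospho_sim
        with pytest.raises(KeyError):
            table.condition_matrix("no-such-contrast")


class TestBHAdjust:
    def test_worked_example(self):
        np.testing.assert_allclose(bh_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_equal_ps_unchanged_and_singleton(self):
        np.testing.assert_allclose(bh_adjust([0.2, 0.2, 0.2]), [0.2, 0.2, 0.2])
        np.testing.assert_allclose(bh_adjust([0.007]), [0.007])

    def test_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(12)
        p = rng.uniform(size=200)
        _, q_ref, _, _ = multipletests(p, method="fdr_bh")
        np.testing.assert_allclose(bh_adjust(p), q_ref, atol=1e-12)

    def test_never_decreases_and_order_invariant(self):
        rng = np.random.default_rng(13)
        p = rng.uniform(size=50)
        q = bh_adjust(p)
        assert np.all(q >= p - 1e-15)
        perm = rng.permutation(50)
        np.testing.assert_allclose(bh_adjust(p[perm]), q[perm], atol=1e-15)

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])

    def test_nan_passthrough(self):
        q = bh_adjust([0.01, np.nan, 0.04])
        assert np.isnan(q[1]) and not np.isnan(q[0])
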