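import numpy as np
import pytest
from scipy import stats

from ebmdea import (
    adjust_inputs,
    fit_slack_frontier,
    jlms_decompose,
    lr_mixed_chisq_test,
)

BETA = np.array([2.0, -1.0, 0.5])


def _simulate(n, sigma_u, sigma_v, seed):
    rng = np.random.default_rng(seed)
    Z = rng.normal(0, 1, (n, 2))
    u = np.abs(rng.normal(0, sigma_u, n)) if sigma_u > 0 else np.zeros(n)
    v = rng.normal(0, sigma_v, n)
    S = BETA[0] + Z @ BETA[1:] + u + v
    return S, Z


class TestFitSlackFrontier:
    def test_recovers_known_parameters(self):
        # sigma_u=1, sigma_v=0.5 -> gamma = 1/1.25 = 0.8
        S, Z = _simulate(2000, 1.0, 0.5, seed=123)
        model = fit_slack_frontier(S, Z)
        np.testing.assert_allclose(model.beta, BETA, atol=0.1)
        assert model.gamma == pytest.approx(0.8, abs=0.07)
        assert model.converged

    def test_no_inefficiency_limit_reduces_to_ols(self):
        S, Z = _simulate(400, 0.0, 0.5, seed=0)
        model = fit_slack_frontier(S, Z)
        Zd = np.column_stack([np.ones(len(S)), Z])
        beta_ols, *_ = np.linalg.lstsq(Zd, S, rcond=None)
        # slopes match OLS tightly; the intercept can shift by the (small)
        # spurious E[u] when gamma is not pinned at the boundary
        np.testing.assert_allclose(model.beta[1:], beta_ols[1:], atol=1e-3)
        assert model.gamma < 0.3

    def test_loglik_dominates_ols_and_fixed_gamma_candidates(self):
        S, Z = _simulate(500, 1.0, 0.5, seed=7)
        model = fit_slack_frontier(S, Z)
        Zd = np.column_stack([np.ones(len(S)), Z])
        beta_ols, *_ = np.linalg.lstsq(Zd, S, rcond=None)
        resid = S - Zd @ beta_ols
        s2 = float(resid @ resid) / len(S)
        ll_ols = -0.5 * len(S) * (np.log(2 * np.pi * s2) + 1.0)
        assert model.loglik >= ll_ols - 1e-6
        # likelihood at the optimum beats the (OLS beta, gamma=0.5) candidate
        from ebmdea.sfa import _loglik
        cand = np.concatenate([beta_ols, [np.log(2 * s2), 0.0]])
        assert model.loglik >= _loglik(cand, S, Zd) - 1e-6

    def test_consistency_bias_shrinks_with_n(self):
        err = {}
        for n in (200, 2000):
            S, Z = _simulate(n, 1.0, 0.5, seed=99)
            model = fit_slack_frontier(S, Z)
            err[n] = np.abs(model.beta - BETA).max() \
                + abs(model.gamma - 0.8)
        assert err[2000] < err[200]

    def test_positive_covariate_effect_has_positive_coefficient(self):
        # a covariate that inflates slack must come back with a + sign
        S, Z = _simulate(800, 0.8, 0.3, seed=5)
        model = fit_slack_frontier(S, Z)
        assert model.beta[2] > 0 and model.beta[1] < 0


class TestJlmsDecompose:
    def test_exact_additivity_and_nonnegativity(self):
        S, Z = _simulate(300, 1.0, 0.5, seed=11)
        model = fit_slack_frontier(S, Z)
        dec = jlms_decompose(S, Z, model)
        np.testing.assert_allclose(dec.f_hat + dec.u_hat + dec.v_hat, S,
                                   atol=1e-10)
        assert np.all(dec.u_hat >= 0)

    def test_mean_u_matches_half_normal_moment(self):
        # E[u] = sigma_u * sqrt(2/pi)
        S, Z = _simulate(200, 1.0, 0.5, seed=21)
        model = fit_slack_frontier(S, Z)
        dec = jlms_decompose(S, Z, model)
        assert dec.u_hat.mean() == pytest.approx(np.sqrt(2 / np.pi), rel=0.15)

    def test_noise_only_limit(self):
        S, Z = _simulate(400, 0.0, 0.5, seed=0)
        model = fit_slack_frontier(S, Z)
        dec = jlms_decompose(S, Z, model)
        resid = S - np.column_stack([np.ones(len(S)), Z]) @ model.beta
        if model.gamma == 0.0:
            np.testing.assert_allclose(dec.v_hat, resid, atol=1e-10)
            assert np.all(dec.u_hat == 0)
        else:   # tiny spurious gamma: u_hat collapses toward a constant
            assert dec.u_hat.std() < 0.3 * np.std(resid)

    def test_extreme_residuals_do_not_underflow(self):
        S, Z = _simulate(50, 1.0, 0.5, seed=3)
        model = fit_slack_frontier(S, Z)
        S2 = S.copy()
        S2[0] -= 50.0      # extreme negative residual
        dec = jlms_decompose(S2, Z, model)
        assert np.all(np.isfinite(dec.u_hat)) and np.all(dec.u_hat >= 0)


class TestAdjustInputs:
    def test_worked_example(self):
        X = np.array([10.0, 10.0])
        f = np.array([3.0, 5.0])
        v = np.array([0.2, -0.1])
        np.testing.assert_allclose(adjust_inputs(X, f, v), [12.0, 10.3])

    def test_homogeneous_environment_no_adjustment(self):
        X = np.array([4.0, 5.0, 6.0])
        assert np.all(adjust_inputs(X, np.full(3, 1.1), np.full(3, -0.2)) == X)

    def test_adjustment_nonnegative_and_argmax_untouched(self):
        rng = np.random.default_rng(17)
        for _ in range(20):
            n = rng.integers(3, 12)
            X = rng.uniform(1, 10, n)
            f = rng.normal(0, 1, n)
            v = rng.normal(0, 1, n)
            adj = adjust_inputs(X, f, v)
            assert np.all(adj >= X - 1e-12)
            if f.argmax() == v.argmax():
                k = f.argmax()
                assert adj[k] == pytest.approx(X[k])
                assert (adj - X).min() == pytest.approx(0.0, abs=1e-12)

    def test_length_mismatch_raises(self):
        with pytest.raises(ValueError):
            adjust_inputs(np.ones(3), np.ones(2), np.ones(3))


class TestMixedChisqTest:
    def test_zero_statistic_never_significant(self):
        res = lr_mixed_chisq_test(0.0, df=1, level=0.05)
        assert not res.reject and res.p_value == 1.0

    def test_df1_critical_value_closed_form(self):
        # equal mixture of chi2_0 and chi2_1: crit solves 0.5*sf_chi2(x,1)=.05
        res = lr_mixed_chisq_test(1.0, df=1, level=0.05)
        assert res.critical_value == pytest.approx(stats.chi2.isf(0.1, 1),
                                                   abs=1e-6)
        assert res.critical_value == pytest.approx(2.706, abs=5e-4)

    def test_size_under_null_near_nominal(self):
        # LR statistics simulated under gamma = 0 via the known asymptotic
        # mixture: rejection rate should sit near 5%
        rng = np.random.default_rng(8)
        reps = 500
        draws = np.where(rng.random(reps) < 0.5, 0.0,
                         rng.chisquare(1, reps))
        rate = np.mean([lr_mixed_chisq_test(x, 1).reject for x in draws])
        assert rate == pytest.approx(0.05, abs=0.03)

    def test_df_below_one_rejected(self):
        with pytest.raises(ValueError):
            lr_mixed_chisq_test(1.0, df=0)
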