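"""AR-error regression machinery: OLS stage, Durbin-Watson, Yule-Walker,
stepwise order selection, feasible GLS."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from itsar import (
    SimulationConfig,
    StudyDesign,
    ar_acovf,
    build_design,
    durbin_watson,
    fit_gls,
    ols_fit,
    select_order,
    simulate_series,
    stepwise_lags,
    yule_walker,
)
from itsar.errors import (
    DomainError,
    OverparameterizationError,
    SingularDesignError,
)

from conftest import JULY_2011, ar1_noise, noiseless_series


# ---------------------------------------------------------------------------
# OLS
# ---------------------------------------------------------------------------

class TestOLS:
    def test_perfect_linear_fit_has_zero_residuals(self, plain_design):
        s, _, _ = noiseless_series((150.0, -0.5, 0.0, 0.0))
        dm = build_design(s, plain_design)
        res = ols_fit(dm)
        np.testing.assert_allclose(res.residuals, 0.0, atol=1e-9)
        np.testing.assert_allclose(res.beta, [150.0, -0.5, 0.0, 0.0], atol=1e-9)

    def test_pure_step_recovered_exactly(self, plain_design):
        s, _, _ = noiseless_series((100.0, 0.0, 5.0, 0.0))
        dm = build_design(s, plain_design)
        res = ols_fit(dm)
        np.testing.assert_allclose(res.beta, [100.0, 0.0, 5.0, 0.0], atol=1e-9)

    def test_matches_normal_equations_oracle(self, plain_design):
        """Brute-force (X'X)^-1 X'y agrees with the least-squares solution."""
        s, _ = simulate_series(SimulationConfig(seasonal=0.0), seed=11)
        dm = build_design(s, plain_design)
        res = ols_fit(dm)
        oracle = np.linalg.solve(dm.X.T @ dm.X, dm.X.T @ dm.y)
        np.testing.assert_allclose(res.beta, oracle, atol=1e-8)

    def test_rank_deficiency_raises(self, plain_design):
        s, _ = simulate_series(SimulationConfig(seasonal=0.0), seed=11)
        dm = build_design(s, plain_design)
        X = dm.X.copy()
        X[:, 3] = X[:, 1] * 2.0  # duplicate a column
        from dataclasses import replace
        with pytest.raises(SingularDesignError):
            ols_fit(replace(dm, X=X))


# ---------------------------------------------------------------------------
# Durbin-Watson
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("resid,lag,expected", [
    ([1, -1, 1, -1], 1, 3.0),
    ([1, 1, 1, 1], 1, 0.0),
    ([1, -1, 1, -1], 2, 0.0),
])
def test_durbin_watson_hand_values(resid, lag, expected):
    assert durbin_watson(resid, lag) == pytest.approx(expected, abs=1e-12)


def test_durbin_watson_undefined_for_zero_residuals():
    with pytest.raises(DomainError):
        durbin_watson([0.0, 0.0, 0.0], 1)
    with pytest.raises(DomainError):
        durbin_watson([1.0, 2.0], 5)


@settings(derandomize=True, max_examples=50, deadline=None)
@given(e=hnp.arrays(np.float64, st.integers(5, 60),
                    elements=st.floats(-1e6, 1e6)),
       lag=st.integers(1, 4))
def test_durbin_watson_bounded_0_4(e, lag):
    if np.sum(e * e) == 0:
        return
    d = durbin_watson(e, lag)
    assert 0.0 <= d <= 4.0 + 1e-12


# ---------------------------------------------------------------------------
# Yule-Walker
# ---------------------------------------------------------------------------

class TestYuleWalker:
    def test_hand_value(self):
        phi, sigma2, _ = yule_walker([1.0, 1.0, -1.0, -1.0], 1)
        assert phi[0] == pytest.approx(0.25, abs=1e-12)
        assert sigma2 == pytest.approx(1.0 - 0.25 * 0.25, abs=1e-12)

    def test_white_noise_phi_near_zero(self):
        rng = np.random.default_rng(0)
        phi, _, _ = yule_walker(rng.normal(size=10_000), 1)
        assert abs(phi[0]) < 0.03

    def test_consistency_on_ar1(self):
        rng = np.random.default_rng(1)
        e = ar1_noise(rng, 10_000, 0.6)
        phi, sigma2, _ = yule_walker(e, 1)
        assert 0.57 <= phi[0] <= 0.63
        assert sigma2 == pytest.approx(1.0, rel=0.1)

    @pytest.mark.parametrize("order", [1, 2, 3])
    def test_matches_statsmodels_mle_autocovariances(self, order):
        sm_yw = pytest.importorskip("statsmodels.regression.linear_model").yule_walker
        rng = np.random.default_rng(2)
        e = ar1_noise(rng, 400, 0.5)
        phi, sigma2, _ = yule_walker(e, order)
        rho, sigma = sm_yw(e, order=order, method="mle", demean=False)
        np.testing.assert_allclose(phi, rho, rtol=1e-10)
        assert sigma2 == pytest.approx(sigma**2, rel=1e-10)

    def test_subset_lags_solve_restricted_moment_equations(self):
        rng = np.random.default_rng(3)
        e = ar1_noise(rng, 500, 0.5)
        lags = [1, 12]
        phi, sigma2, _ = yule_walker(e, lags)
        # independent check of the restricted system
        n = len(e)
        c = np.array([e[j:] @ e[:n - j] for j in range(13)]) / n
        C = np.array([[c[abs(i - j)] for j in lags] for i in lags])
        expect = np.linalg.solve(C, c[lags])
        np.testing.assert_allclose(phi, expect, rtol=1e-10)
        assert sigma2 == pytest.approx(c[0] - expect @ c[lags], rel=1e-10)

    def test_too_few_residuals(self):
        with pytest.raises(DomainError):
            yule_walker([1.0, 2.0], 1)


def test_ar_acovf_matches_statsmodels():
    arma_acovf = pytest.importorskip("statsmodels.tsa.arima_process").arma_acovf
    phi = np.array([0.6, -0.25])
    mine = ar_acovf(phi, 1.7, 12)
    ref = arma_acovf(np.r_[1.0, -phi], np.ones(1), nobs=12, sigma2=1.7)
    np.testing.assert_allclose(mine, ref, rtol=1e-10)


# ---------------------------------------------------------------------------
# Stepwise order selection
# ---------------------------------------------------------------------------

class TestSelectOrder:
    def test_max_lag_zero_reduces_to_ols(self, study_design):
        s, _ = simulate_series(SimulationConfig(), seed=9)
        dm = build_design(s, study_design)
        assert select_order(dm, max_lag=0) == frozenset()

    def test_white_noise_usually_empty(self):
        rng = np.random.default_rng(4)
        hits = sum(bool(stepwise_lags(rng.normal(size=200), 13, 0.05))
                   for _ in range(50))
        assert hits <= 10  # retention should be rare under the null

    def test_ar1_lag_detected(self):
        rng = np.random.default_rng(5)
        found = sum(1 in stepwise_lags(ar1_noise(rng, 200, 0.7), 13, 0.05)
                    for _ in range(20))
        assert found >= 18

    def test_max_lag_clamped_below_quarter_of_n(self):
        rng = np.random.default_rng(6)
        lags = stepwise_lags(rng.normal(size=35), max_lag=13)
        assert all(l <= 8 for l in lags)


# ---------------------------------------------------------------------------
# Feasible GLS
# ---------------------------------------------------------------------------

class TestFitGLS:
    def test_empty_lags_reduce_to_classical_ols(self, noisy_series, study_design):
        sm_api = pytest.importorskip("statsmodels.api")
        s, _ = noisy_series
        dm = build_design(s, study_design)
        fit = fit_gls(dm, frozenset())
        ref = sm_api.OLS(dm.y, dm.X).fit()
        np.testing.assert_allclose(fit.beta, ref.params, rtol=1e-10, atol=1e-12)
        np.testing.assert_allclose(fit.se, ref.bse, rtol=1e-10, atol=1e-12)
        np.testing.assert_allclose(fit.p_values, ref.pvalues, rtol=1e-8, atol=1e-12)
        assert fit.df_resid == int(ref.df_resid)

    def test_noiseless_fit_has_unit_r2(self, plain_design):
        s, _, _ = noiseless_series((150.0, -0.5, -10.0, -1.0))
        fit = fit_gls(build_design(s, plain_design), frozenset())
        assert fit.r2_total == pytest.approx(1.0, abs=1e-12)

    def test_agrees_with_statsmodels_gls_oracle(self, study_design):
        """Feasible GLS with AR(1) whitening reproduces an independently
        assembled GLS (statsmodels) with the same AR covariance."""
        sm_lm = pytest.importorskip("statsmodels.regression.linear_model")
        arma_acovf = pytest.importorskip("statsmodels.tsa.arima_process").arma_acovf
        from scipy.linalg import toeplitz

        s, _ = simulate_series(SimulationConfig(), seed=21)
        dm = build_design(s, study_design)
        fit = fit_gls(dm, {1})

        resid = ols_fit(dm).residuals
        rho, _ = sm_lm.yule_walker(resid, order=1, method="mle", demean=False)
        acov = arma_acovf(np.r_[1.0, -rho], np.ones(1), nobs=dm.n, sigma2=1.0)
        ref = sm_lm.GLS(dm.y, dm.X, sigma=toeplitz(acov)).fit()
        np.testing.assert_allclose(fit.beta, ref.params, rtol=1e-6)
        assert fit.phi[0] == pytest.approx(rho[0], rel=1e-10)

    def test_projection_adjusted_ar_removes_detrending_bias(self, plain_design):
        """Plain Yule-Walker on detrended short-series residuals is biased
        toward zero; the projection-moment-matched estimator recovers the
        generating AR coefficient on average."""
        from itsar.ar import projection_adjusted_ar
        plain, adjusted = [], []
        for seed in range(60):
            s, _ = simulate_series(SimulationConfig(seasonal=0.0), seed=300 + seed)
            dm = build_design(s, plain_design)
            fit = fit_gls(dm, {1})
            plain.append(fit.phi[0])
            phi_adj, sigma2_adj = projection_adjusted_ar(dm.X, fit.residuals, {1})
            adjusted.append(phi_adj[0])
            assert sigma2_adj > 0
        # generating phi = 0.5: plain estimate is far low, adjusted is close
        assert np.mean(plain) < 0.38
        assert abs(np.mean(adjusted) - 0.5) < 0.08

    def test_whitening_removes_autocorrelation_at_known_phi(self):
        """Whitening by the exact stationary covariance factor leaves
        innovations with negligible lag-1 autocorrelation (n = 1000)."""
        from scipy.linalg import cholesky, solve_triangular, toeplitz
        rng = np.random.default_rng(7)
        phi = 0.6
        e = ar1_noise(rng, 1000, phi)
        gamma = ar_acovf(np.array([phi]), 1.0, len(e))
        L = cholesky(toeplitz(gamma), lower=True)
        w = solve_triangular(L, e, lower=True)
        r1 = np.corrcoef(w[1:], w[:-1])[0, 1]
        assert abs(r1) <= 0.1

    def test_ar_r2_not_below_ols_r2(self, study_design):
        for seed in range(5):
            s, _ = simulate_series(SimulationConfig(), seed=200 + seed)
            dm = build_design(s, study_design)
            r2_ols = fit_gls(dm, frozenset()).r2_total
            r2_ar = fit_gls(dm, {1}).r2_total
            assert r2_ar >= r2_ols - 1e-9

    def test_overparameterization_rejected(self):
        s, _, _ = noiseless_series((100.0, 0.0, -5.0, 0.0), seasonal=5.0,
                                   n_pre=6, n_post=6)
        d = StudyDesign(advisory_month=s.months[6], n_pre=6, n_post=6)
        dm = build_design(s, d)
        with pytest.raises(OverparameterizationError):
            fit_gls(dm, frozenset())

    def test_coefficient_table_layout(self, noisy_series, study_design):
        s, _ = noisy_series
        fit = fit_gls(build_design(s, study_design), {1})
        tbl = fit.coef_table()
        assert list(tbl.columns) == ["term", "estimate", "se", "p_value"]
        assert list(tbl["term"][:4]) == ["intercept", "time", "step", "post_trend"]
        assert ((tbl["p_value"] >= 0) & (tbl["p_value"] <= 1)).all()
        diag = fit.diagnostics()
        assert 0.0 <= diag["r2_total"] <= 1.0
        assert diag["lags"] == "1"
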