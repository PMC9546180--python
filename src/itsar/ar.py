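"""Segmented regression with autoregressive errors.

The error term of the interrupted time series model is allowed to follow a
stationary AR(p) process. Estimation is two-step feasible generalized least
squares in the Yule-Walker tradition:

1. ordinary least squares on the segmented design;
2. Yule-Walker estimation of the AR parameters from the OLS residuals
   (method-of-moments on sample autocovariances, a Toeplitz system);
3. exact whitening of response and design using the Cholesky factor of the
   implied stationary error covariance — the first p observations are scaled
   by the stationary covariance factor rather than dropped, which matters at
   the short series lengths typical of monthly advisory studies (n ~ 35);
4. OLS on the whitened data, with degrees of freedom charged for both the
   regression and the AR parameters.

Autocorrelation is detected with generalized Durbin-Watson statistics and the
AR order chosen by backward (stepwise) elimination of non-significant lags.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg, stats

from .design import SegmentedDesignMatrix
from .errors import (
    DomainError,
    OverparameterizationError,
    SingularDesignError,
    StationarityError,
)

__all__ = [
    "OLSResult",
    "ARSegmentedFit",
    "ols_fit",
    "durbin_watson",
    "yule_walker",
    "stepwise_lags",
    "select_order",
    "fit_gls",
    "ar_acovf",
]


# ---------------------------------------------------------------------------
# OLS first stage
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class OLSResult:
    beta: np.ndarray
    residuals: np.ndarray
    fitted: np.ndarray


def _check_rank(X: np.ndarray) -> None:
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise SingularDesignError(
            f"design matrix is rank deficient ({X.shape[0]}x{X.shape[1]})"
        )


def ols_fit(design: SegmentedDesignMatrix) -> OLSResult:
    """Ordinary least squares on the segmented design.

    Raises
    ------
    SingularDesignError
        If the design matrix is rank deficient.
    """
    X, y = design.X, design.y
    _check_rank(X)
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    fitted = X @ beta
    return OLSResult(beta=beta, residuals=y - fitted, fitted=fitted)


# ---------------------------------------------------------------------------
# Durbin-Watson
# ---------------------------------------------------------------------------

def durbin_watson(residuals, lag: int = 1) -> float:
    """Generalized Durbin-Watson statistic at the given lag.

    ``d_j = sum_{t>j} (e_t - e_{t-j})^2 / sum_t e_t^2``; values near 2
    indicate no lag-``j`` autocorrelation, near 0 positive, near 4 negative.
    """
    e = np.asarray(residuals, dtype=float)
    if not 1 <= lag < len(e):
        raise DomainError(f"lag must be in 1..{len(e) - 1}, got {lag}")
    denom = float(np.sum(e * e))
    if denom == 0.0:
        raise DomainError("Durbin-Watson undefined for all-zero residuals")
    num = float(np.sum((e[lag:] - e[:-lag]) ** 2))
    return num / denom


# ---------------------------------------------------------------------------
# Yule-Walker
# ---------------------------------------------------------------------------

def _sample_autocov(e: np.ndarray, maxlag: int) -> np.ndarray:
    """Biased sample autocovariances c_0..c_maxlag (divisor n, no demeaning:
    OLS residuals from a design with an intercept already sum to zero)."""
    n = len(e)
    return np.array([e[j:] @ e[: n - j] for j in range(maxlag + 1)]) / n


def _check_stationary(phi_full: np.ndarray) -> None:
    """phi_full[j-1] is the coefficient at lag j (zeros allowed)."""
    if len(phi_full) == 0:
        return
    # roots of 1 - phi_1 z - ... - phi_p z^p must lie outside the unit circle
    coeffs = np.concatenate([-phi_full[::-1], [1.0]])  # highest power first
    roots = np.roots(coeffs)
    if np.any(np.abs(roots) <= 1.0 + 1e-10):
        raise StationarityError(
            f"estimated AR parameters are nonstationary (min |root| = "
            f"{np.min(np.abs(roots)):.4f})"
        )


def yule_walker(residuals, lags) -> tuple[np.ndarray, float, np.ndarray]:
    """Yule-Walker estimates for an AR model on the given lags.

    ``lags`` may be an integer order p (lags 1..p) or a sorted collection of
    positive lags (a subset model, as produced by stepwise elimination). The
    moment equations ``sum_j phi_j c_{|l_i - l_j|} = c_{l_i}`` are solved on
    the requested lags only.

    Returns
    -------
    phi : array aligned with the requested lags.
    sigma2 : innovation variance ``c_0 - phi . r``.
    phi_se : approximate standard errors of ``phi`` from the Yule-Walker
        information matrix, ``sqrt(sigma2/n * diag(C^{-1}))``.

    Raises
    ------
    StationarityError
        If the solution implies a nonstationary process.
    """
    e = np.asarray(residuals, dtype=float)
    if isinstance(lags, (int, np.integer)):
        lag_list = list(range(1, int(lags) + 1))
    else:
        lag_list = sorted(int(l) for l in lags)
    if not lag_list or min(lag_list) < 1:
        raise DomainError("lags must be positive integers")
    p = max(lag_list)
    if len(e) < p + 2:
        raise DomainError(f"need at least {p + 2} residuals for max lag {p}")

    c = _sample_autocov(e, p)
    r = c[lag_list]
    C = np.array([[c[abs(i - j)] for j in lag_list] for i in lag_list])
    try:
        if lag_list == list(range(1, p + 1)):
            phi = linalg.solve_toeplitz(c[:p], r)
        else:
            phi = linalg.solve(C, r, assume_a="sym")
    except (linalg.LinAlgError, np.linalg.LinAlgError) as exc:
        raise SingularDesignError(f"singular autocovariance matrix: {exc}") from exc
    if not np.all(np.isfinite(phi)):
        raise SingularDesignError("singular autocovariance matrix")

    sigma2 = float(c[0] - phi @ r)
    phi_full = np.zeros(p)
    phi_full[np.array(lag_list) - 1] = phi
    _check_stationary(phi_full)

    try:
        Cinv = linalg.inv(C)
    except linalg.LinAlgError as exc:  # pragma: no cover - guarded above
        raise SingularDesignError(str(exc)) from exc
    phi_se = np.sqrt(np.maximum(sigma2 / len(e) * np.diag(Cinv), 0.0))
    return phi, sigma2, phi_se


def ar_acovf(phi_full: np.ndarray, sigma2: float, nobs: int) -> np.ndarray:
    """Theoretical autocovariances gamma_0..gamma_{nobs-1} of a stationary
    AR(p) process with innovation variance ``sigma2``.

    Solves the extended Yule-Walker system for gamma_0..gamma_p, then runs the
    recursion ``gamma_k = sum_j phi_j gamma_{k-j}``.
    """
    p = len(phi_full)
    if p == 0:
        out = np.zeros(nobs)
        out[0] = sigma2
        return out
    # Linear system in gamma_0..gamma_p:
    #   gamma_0 - sum_j phi_j gamma_j                    = sigma2
    #   gamma_k - sum_j phi_j gamma_{|k-j|}              = 0      (k = 1..p)
    A = np.zeros((p + 1, p + 1))
    b = np.zeros(p + 1)
    b[0] = sigma2
    for k in range(p + 1):
        A[k, k] += 1.0
        for j in range(1, p + 1):
            A[k, abs(k - j)] -= phi_full[j - 1]
    gamma = np.linalg.solve(A, b)
    out = np.zeros(max(nobs, p + 1))
    out[: p + 1] = gamma
    for k in range(p + 1, nobs):
        out[k] = phi_full @ out[k - 1 : k - p - 1 : -1] if p > 1 else phi_full[0] * out[k - 1]
    return out[:nobs]


def _stationary_full(phi_full: np.ndarray, margin: float = 1.005) -> bool:
    if len(phi_full) == 0:
        return True
    coeffs = np.concatenate([-phi_full[::-1], [1.0]])
    return bool(np.all(np.abs(np.roots(coeffs)) > margin))


def reml_ar(X: np.ndarray, y: np.ndarray, lags) -> tuple[np.ndarray, float, np.ndarray]:
    """Restricted maximum likelihood estimates of the AR error parameters of
    a linear regression, with their approximate sampling covariance.

    REML maximizes the likelihood of error contrasts, so — unlike plain
    Yule-Walker on residuals — it is not biased by the loss of low-frequency
    error variation to the fitted trend/step regressors, which is severe in
    short advisory windows. The covariance comes from the curvature of the
    restricted log-likelihood at the optimum (finite differences) and feeds
    the bootstrap's propagation of AR-parameter uncertainty.

    Returns
    -------
    phi : REML AR coefficients aligned with the sorted ``lags``.
    sigma2 : profiled innovation variance.
    cov : approximate covariance matrix of ``phi``.

    Falls back to the Yule-Walker solution (with its information-matrix
    covariance) if the optimisation fails.
    """
    from scipy import optimize

    y = np.asarray(y, dtype=float)
    n, k = X.shape
    lag_list = sorted(int(l) for l in lags)
    if not lag_list:
        raise DomainError("need at least one lag")
    p = max(lag_list)
    idx = np.array(lag_list) - 1

    def embed(vec):
        full = np.zeros(p)
        full[idx] = vec
        return full

    def profile(phi_full):
        """Whitened regression at fixed phi: returns the -2 restricted
        log-likelihood (up to a constant) and the profiled sigma2."""
        V = linalg.toeplitz(ar_acovf(phi_full, 1.0, n))
        L = linalg.cholesky(V, lower=True)
        Xw = linalg.solve_triangular(L, X, lower=True)
        yw = linalg.solve_triangular(L, y, lower=True)
        beta, *_ = np.linalg.lstsq(Xw, yw, rcond=None)
        r = yw - Xw @ beta
        s2 = float(r @ r) / (n - k)
        logdet_v = 2.0 * float(np.sum(np.log(np.diag(L))))
        _, logdet_xx = np.linalg.slogdet(Xw.T @ Xw)
        return logdet_v + logdet_xx + (n - k) * np.log(s2), s2

    def objective(vec):
        full = embed(np.atleast_1d(vec))
        if not _stationary_full(full, margin=1.02):
            return 1e12
        try:
            val, _ = profile(full)
        except (linalg.LinAlgError, FloatingPointError):
            return 1e12
        return val

    try:
        if len(lag_list) == 1:
            res = optimize.minimize_scalar(objective, bounds=(-0.95, 0.95),
                                           method="bounded")
            phi_hat = np.atleast_1d(res.x)
            ok = res.fun < 1e11
        else:
            phi0, _, _ = yule_walker(y - X @ np.linalg.lstsq(X, y, rcond=None)[0],
                                     lag_list)
            res = optimize.minimize(objective, np.clip(phi0, -0.8, 0.8),
                                    method="Nelder-Mead",
                                    options={"xatol": 1e-5, "fatol": 1e-7})
            phi_hat = np.atleast_1d(res.x)
            ok = res.success and res.fun < 1e11
    except Exception:
        ok = False

    if not ok:
        beta0, *_ = np.linalg.lstsq(X, y, rcond=None)
        phi_yw, sigma2_yw, phi_se = yule_walker(y - X @ beta0, lag_list)
        return phi_yw, sigma2_yw, np.diag(phi_se**2)

    _, sigma2 = profile(embed(phi_hat))

    # curvature of the -2 restricted log-likelihood -> Var(phi) ~ 2 H^-1
    m = len(lag_list)
    h = 1e-2
    H = np.zeros((m, m))
    f0 = objective(phi_hat)
    for i in range(m):
        ei = np.zeros(m); ei[i] = h
        for j in range(i, m):
            ej = np.zeros(m); ej[j] = h
            if i == j:
                H[i, i] = (objective(phi_hat + ei) + objective(phi_hat - ei)
                           - 2 * f0) / h**2
            else:
                H[i, j] = H[j, i] = (
                    objective(phi_hat + ei + ej) - objective(phi_hat + ei)
                    - objective(phi_hat + ej) + f0
                ) / h**2
    try:
        cov = 2.0 * np.linalg.inv(H)
        if np.any(np.diag(cov) <= 0):
            raise np.linalg.LinAlgError
    except np.linalg.LinAlgError:
        fallback_var = np.array([(1.0 - min(v**2, 0.96)) / n for v in phi_hat])
        cov = np.diag(fallback_var)
    return phi_hat, float(sigma2), cov


def projection_adjusted_ar(X: np.ndarray, residuals, lags) -> tuple[np.ndarray, float]:
    """AR parameters corrected for the detrending-projection bias.

    Residuals from a regression are ``v = M e`` with ``M = I - X(X'X)^-1 X'``;
    the projection absorbs low-frequency error variation, so their sample
    autocovariances — and hence plain Yule-Walker estimates — are biased
    toward zero, severely in short windows with trend and step regressors.
    This method-of-moments correction finds the AR parameters whose *implied
    expected* residual autocovariances,

        E[c_j] = sigma^2 * offdiag_j(M Gamma(phi) M) / n,

    match the observed ones (autocorrelation ratios determine ``phi``, the
    level determines ``sigma^2``). Falls back to the plain Yule-Walker
    solution if the root search fails or leaves the stationary region.

    Used to build the bootstrap's error-generating process; reported fits
    keep the plain Yule-Walker estimates.
    """
    from scipy import optimize

    e = np.asarray(residuals, dtype=float)
    n = len(e)
    lag_list = sorted(int(l) for l in lags)
    if not lag_list:
        raise DomainError("need at least one lag")
    p = max(lag_list)
    phi_yw, sigma2_yw, _ = yule_walker(e, lag_list)

    c_obs = _sample_autocov(e, p)
    if c_obs[0] <= 0:
        return phi_yw, sigma2_yw

    Q, _ = np.linalg.qr(X)
    M = np.eye(n) - Q @ Q.T

    def implied(phi_vec):
        phi_full = np.zeros(p)
        phi_full[np.array(lag_list) - 1] = phi_vec
        coeffs = np.concatenate([-phi_full[::-1], [1.0]])
        if np.any(np.abs(np.roots(coeffs)) <= 1.005):  # keep well inside stationarity
            return None
        G = M @ linalg.toeplitz(ar_acovf(phi_full, 1.0, n)) @ M
        c0 = np.trace(G)
        cj = np.array([np.trace(G, offset=j) for j in lag_list])
        return c0, cj

    def ratio_gap(phi_vec):
        res = implied(phi_vec)
        if res is None:
            return np.full(len(lag_list), 1e6)
        c0, cj = res
        return cj / c0 - c_obs[lag_list] / c_obs[0]

    sol = optimize.root(ratio_gap, np.clip(phi_yw, -0.9, 0.9), method="hybr")
    phi_adj = sol.x
    res = implied(phi_adj)
    if not sol.success or res is None:
        return phi_yw, sigma2_yw
    c0_implied, _ = res
    # innovation variance matching the observed residual variance level
    sigma2_adj = float(n * c_obs[0] / c0_implied)
    return phi_adj, sigma2_adj


# ---------------------------------------------------------------------------
# Stepwise order selection
# ---------------------------------------------------------------------------

def stepwise_lags(residuals, max_lag: int = 13, alpha: float = 0.05) -> frozenset[int]:
    """Backward stepwise elimination of AR lags on a residual series.

    Starts from lags 1..max_lag fitted jointly by Yule-Walker, repeatedly
    drops the lag whose approximate t-statistic has the largest p-value
    (ties broken by dropping the higher lag), and stops when every retained
    lag is significant or none remain. ``max_lag`` is clamped to stay below a
    quarter of the series length.

    ``alpha`` is the family-wise significance level of the whole search: each
    lag is tested against ``alpha / max_lag`` (Bonferroni). Backward
    elimination keeps, at each stage, the *most* significant of the candidate
    lags, so an unadjusted per-lag threshold would retain a spurious lag for
    white noise with probability near ``1 - (1-alpha)^max_lag`` (about half,
    at the defaults); the adjustment keeps the false-retention rate at or
    below ``alpha``.
    """
    e = np.asarray(residuals, dtype=float)
    n = len(e)
    max_lag = min(int(max_lag), (n - 1) // 4)
    if max_lag < 1:
        return frozenset()
    threshold = alpha / max_lag
    lags = list(range(1, max_lag + 1))
    while lags:
        phi, _, phi_se = yule_walker(e, lags)
        with np.errstate(divide="ignore", invalid="ignore"):
            z = np.where(phi_se > 0, phi / phi_se, np.inf)
        pvals = 2.0 * stats.norm.sf(np.abs(z))
        worst = np.max(pvals)
        if worst <= threshold:
            break
        # ties: drop the highest of the worst lags
        drop = max(l for l, pv in zip(lags, pvals) if pv == worst)
        lags.remove(drop)
    return frozenset(lags)


def select_order(design: SegmentedDesignMatrix, max_lag: int = 13,
                 alpha: float = 0.05) -> frozenset[int]:
    """Select AR lags for a segmented design by stepwise elimination on the
    OLS residuals. Returns a possibly empty set of retained lags."""
    if max_lag <= 0:
        return frozenset()
    return stepwise_lags(ols_fit(design).residuals, max_lag=max_lag, alpha=alpha)


# ---------------------------------------------------------------------------
# Feasible GLS fit
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ARSegmentedFit:
    """Result of a segmented regression with AR errors.

    ``beta``/``se``/``p_values`` are aligned with ``columns`` and expressed in
    rate units (prescriptions per 100 000). ``phi`` is aligned with ``lags``.
    ``residuals`` are structural residuals ``y - X beta`` on the original
    scale. ``dw`` holds generalized Durbin-Watson statistics at lags
    1..len(dw) computed on the OLS residuals.
    """

    beta: np.ndarray
    se: np.ndarray
    p_values: np.ndarray
    columns: tuple[str, ...]
    lags: tuple[int, ...]
    phi: np.ndarray
    sigma2: float
    residuals: np.ndarray
    fitted: np.ndarray
    dw: tuple[float, ...]
    r2_total: float
    df_resid: int
    dm: SegmentedDesignMatrix

    @property
    def phi_full(self) -> np.ndarray:
        """AR coefficients on a dense 1..max(lags) grid (zeros where a lag
        was not retained)."""
        if not self.lags:
            return np.zeros(0)
        full = np.zeros(max(self.lags))
        full[np.array(self.lags) - 1] = self.phi
        return full

    def coef_table(self) -> pd.DataFrame:
        """Coefficient summary (term, estimate, SE, p-value)."""
        return pd.DataFrame({
            "term": list(self.columns),
            "estimate": self.beta,
            "se": self.se,
            "p_value": self.p_values,
        })

    def diagnostics(self) -> dict:
        return {
            "lags": ",".join(map(str, self.lags)),
            "phi": ",".join(f"{v:.6g}" for v in self.phi),
            "sigma2": self.sigma2,
            "r2_total": self.r2_total,
            "df_resid": self.df_resid,
            **{f"dw_{j + 1}": d for j, d in enumerate(self.dw)},
        }


def _one_step_r2(y: np.ndarray, fitted: np.ndarray, phi_full: np.ndarray) -> float:
    """Total R-square from one-step-ahead predictions: the structural fit plus
    the AR forecast of the error, using whatever residual history exists."""
    v = y - fitted
    pred = fitted.copy()
    p = len(phi_full)
    for t in range(len(y)):
        for j in range(1, min(p, t) + 1):
            pred[t] += phi_full[j - 1] * v[t - j]
    sst = float(np.sum((y - y.mean()) ** 2))
    if sst == 0.0:
        raise DomainError("constant response: total R-square undefined")
    return 1.0 - float(np.sum((y - pred) ** 2)) / sst


def fit_gls(design: SegmentedDesignMatrix, lags=frozenset(),
            diagnostics: bool = True) -> ARSegmentedFit:
    """Fit the segmented model with AR errors on the given lags by two-step
    feasible GLS (OLS, Yule-Walker on the residuals, exact whitening, OLS on
    whitened data).

    With an empty lag set the fit reduces exactly to OLS with classical
    standard errors. ``diagnostics=False`` skips the Durbin-Watson and total
    R-square computations and the (redundant) rank re-checks — used by the
    bootstrap, which refits the same validated design thousands of times.

    Raises
    ------
    StationarityError
        The Yule-Walker solution is nonstationary.
    OverparameterizationError
        No residual degrees of freedom remain.
    """
    X, y = design.X, design.y
    n, k = X.shape
    lag_tuple = tuple(sorted(int(l) for l in lags)) if lags else ()
    df_resid = n - k - len(lag_tuple)
    if df_resid <= 0:
        raise OverparameterizationError(
            f"{n} observations cannot support {k} regression and "
            f"{len(lag_tuple)} AR parameters"
        )

    if diagnostics:
        ols = ols_fit(design)
    else:
        beta0, *_ = np.linalg.lstsq(X, y, rcond=None)
        ols = OLSResult(beta=beta0, residuals=y - X @ beta0, fitted=X @ beta0)

    if lag_tuple:
        phi, sigma2, _ = yule_walker(ols.residuals, lag_tuple)
        phi_full = np.zeros(max(lag_tuple))
        phi_full[np.array(lag_tuple) - 1] = phi
        # exact stationary covariance of the AR error, unit innovation scale
        gamma = ar_acovf(phi_full, 1.0, n)
        L = linalg.cholesky(linalg.toeplitz(gamma), lower=True)
        Xw = linalg.solve_triangular(L, X, lower=True)
        yw = linalg.solve_triangular(L, y, lower=True)
    else:
        phi, sigma2 = np.zeros(0), float("nan")
        phi_full = np.zeros(0)
        Xw, yw = X, y

    if diagnostics:
        _check_rank(Xw)
    beta, *_ = np.linalg.lstsq(Xw, yw, rcond=None)
    resid_w = yw - Xw @ beta
    s2 = float(resid_w @ resid_w) / df_resid
    XtX_inv = np.linalg.inv(Xw.T @ Xw)
    se = np.sqrt(np.maximum(s2 * np.diag(XtX_inv), 0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        tvals = np.where(se > 0, beta / se, np.inf)
    p_values = 2.0 * stats.t.sf(np.abs(tvals), df_resid)

    fitted = X @ beta
    residuals = y - fitted
    if not lag_tuple:
        sigma2 = s2

    if diagnostics:
        max_dw = max(1, min(13, (n - 1) // 4))
        ols_resid = ols.residuals
        if np.allclose(ols_resid, 0.0):
            dw = ()
            r2 = 1.0
        else:
            dw = tuple(durbin_watson(ols_resid, j) for j in range(1, max_dw + 1))
            r2 = _one_step_r2(y, fitted, phi_full)
    else:
        dw = ()
        r2 = float("nan")

    return ARSegmentedFit(
        beta=beta, se=se, p_values=p_values, columns=design.columns,
        lags=lag_tuple, phi=phi, sigma2=sigma2, residuals=residuals,
        fitted=fitted, dw=dw, r2_total=r2, df_resid=df_resid, dm=design,
    )
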