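"""Counterfactual extrapolation and bootstrap effect estimation.

The fitted baseline trend (intercept, pre-advisory slope and seasonal terms)
is extrapolated across the post-advisory window to give the use that would
have been expected had the advisory not been issued. The advisory's effect is
the mean percentage difference between the post-advisory trend and that
extrapolated baseline, with a percentile bootstrap confidence interval built
by resampling the whitened innovations of the fitted AR error process.
"""

from __future__ import annotations

from dataclasses import dataclass, replace as dc_replace

import numpy as np
from scipy import signal

from .ar import ARSegmentedFit, _stationary_full, fit_gls, reml_ar, select_order
from .design import StudyDesign, build_design
from .errors import (
    BootstrapInstabilityError,
    CounterfactualDomainError,
    DomainError,
    ItsarError,
)
from .months import MonthIndex
from .timeseries import PrescriptionSeries

__all__ = ["EffectEstimate", "counterfactual", "pct_change", "bootstrap_ci"]

_BOOT_BURNIN = 100


@dataclass(frozen=True)
class EffectEstimate:
    """Mean percentage change versus the extrapolated baseline.

    ``pct_change`` is in percent; negative values are reductions in use.
    ``per_month`` holds one record per post month: (month, expected
    counterfactual rate, post-advisory rate, monthly % difference).
    ``draws`` are the bootstrap replicates behind the percentile CI; their
    standard deviation ``se`` feeds the between-group interaction test.
    """

    group_label: str
    pct_change: float
    ci_low: float
    ci_high: float
    n_boot: int
    seed: int
    per_month: tuple[tuple[MonthIndex, float, float, float], ...]
    draws: np.ndarray | None = None
    n_failed: int = 0

    @property
    def se(self) -> float:
        if self.draws is None or len(self.draws) < 2:
            return float("nan")
        return float(np.std(self.draws, ddof=1))

    @property
    def point_outside_ci(self) -> bool:
        """Percentile CIs can rarely exclude the point estimate; flag it."""
        return not (self.ci_low <= self.pct_change <= self.ci_high)

    def to_record(self) -> dict:
        return {
            "group": self.group_label,
            "pct_change": self.pct_change,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "se": self.se,
            "n_boot": self.n_boot,
            "seed": self.seed,
        }


def counterfactual(fit: ARSegmentedFit) -> np.ndarray:
    """Expected rate in each post-advisory month had the advisory not been
    issued: the deterministic prediction with the step and post-trend terms
    forced to zero.

    Raises
    ------
    CounterfactualDomainError
        If any expected rate is non-positive (percentage change undefined).
    """
    dm = fit.dm
    expected = np.array([dm.baseline_row(m) @ fit.beta for m in dm.design.post_months()])
    if np.any(expected <= 0):
        raise CounterfactualDomainError(
            "extrapolated baseline is non-positive in the post window; "
            "percentage change is undefined"
        )
    return expected


def _post_actuals(fit: ARSegmentedFit, mode: str) -> np.ndarray:
    dm = fit.dm
    if mode == "fitted":
        return np.array([dm.full_row(m) @ fit.beta for m in dm.design.post_months()])
    if mode == "observed":
        return dm.y[dm.post_mask]
    raise DomainError(f"mode must be 'fitted' or 'observed', got {mode!r}")


def pct_change(fit: ARSegmentedFit, mode: str = "fitted") -> float:
    """Mean percentage change over the post window relative to the
    extrapolated baseline.

    ``mode='fitted'`` (default) compares the model-implied post-advisory
    trend with the baseline — a trend-versus-trend contrast; ``'observed'``
    uses the raw observed rates instead.
    """
    expected = counterfactual(fit)
    actual = _post_actuals(fit, mode)
    return float(np.mean(100.0 * (actual - expected) / expected))


def per_month_changes(fit: ARSegmentedFit, mode: str = "fitted"):
    """(month, expected, actual, % difference) for each post month."""
    expected = counterfactual(fit)
    actual = _post_actuals(fit, mode)
    months = fit.dm.design.post_months()
    return tuple(
        (m, float(e), float(a), float(100.0 * (a - e) / e))
        for m, e, a in zip(months, expected, actual)
    )


def _innovations(residuals: np.ndarray, phi_full: np.ndarray) -> np.ndarray:
    """Whiten structural residuals to (approximately) iid innovations by the
    AR recursion; the first p values lack history and are dropped."""
    p = len(phi_full)
    if p == 0:
        pool = residuals.copy()
    else:
        pool = residuals[p:].copy()
        for j in range(1, p + 1):
            pool -= phi_full[j - 1] * residuals[p - j : len(residuals) - j]
    return pool - pool.mean()


def _rebuild_errors(innov_draw: np.ndarray, phi_full: np.ndarray, n: int) -> np.ndarray:
    """Run the AR recursion over resampled innovations, discarding a burn-in
    so the errors start near the stationary distribution."""
    if len(phi_full) == 0:
        return innov_draw[-n:]
    e = signal.lfilter([1.0], np.concatenate([[1.0], -phi_full]), innov_draw)
    return e[-n:]


def bootstrap_ci(
    series: PrescriptionSeries,
    design: StudyDesign,
    n_boot: int = 5000,
    seed: int | None = None,
    lags=None,
    max_lag: int = 13,
    alpha: float = 0.05,
    mode: str = "fitted",
    scheme: str = "innovation",
    block_length: int = 3,
    bias_adjust: bool = True,
    keep_draws: bool = True,
) -> EffectEstimate:
    """Mean percentage change with a percentile bootstrap 95% CI.

    The base model is fitted once (AR lags chosen by stepwise elimination
    unless ``lags`` is given). Every bootstrap iteration resamples the fit's
    whitened innovations with replacement, rebuilds a stationary AR error
    series, adds the base deterministic fit, refits the model with the AR
    order frozen at the base selection, and records the percentage change.
    With ``bias_adjust`` (default) the error-generating AR parameters and
    innovation scale come from REML — immune to the detrending bias that
    shrinks Yule-Walker estimates in short windows — and each iteration draws
    its generating AR parameter from the REML estimate's sampling
    distribution, so the intervals also reflect AR-parameter uncertainty;
    otherwise the base fit's own parameters are reused with a sqrt(n/df)
    variance inflation. CI bounds are the 2.5th and 97.5th percentiles
    (linear interpolation between order statistics). Deterministic given
    ``seed``.

    ``scheme='moving_block'`` resamples blocks of structural residuals of
    length ``block_length`` instead, preserving short-range dependence
    without an AR reconstruction.

    Raises
    ------
    BootstrapInstabilityError
        If more than 5% of bootstrap refits fail.
    """
    if n_boot < 100:
        raise DomainError("n_boot must be at least 100")
    if seed is None:
        raise DomainError("a seed is required for reproducible bootstrap CIs")
    rng = np.random.default_rng(seed)

    dm = build_design(series, design)
    if lags is None:
        lags = select_order(dm, max_lag=max_lag, alpha=alpha)
    lags = frozenset(lags)
    base = fit_gls(dm, lags)
    point = pct_change(base, mode=mode)
    per_month = per_month_changes(base, mode=mode)

    n = dm.n
    # residuals from a fit with k regression and p AR parameters are
    # underdispersed by a factor ~ df/n; rescale so resampled errors carry
    # the full innovation variance (the usual modified-residual correction)
    inflate = np.sqrt(n / base.df_resid)

    # the bootstrap's error-GENERATING process: with bias_adjust the AR
    # parameters and innovation variance come from REML, which is not biased
    # by the loss of low-frequency error variation to the fitted trend/step
    # regressors (plain Yule-Walker on n ~ 35 detrended residuals is biased
    # toward zero, which would make every resampled world less autocorrelated
    # — hence every CI narrower — than the data warrant); each iteration then
    # draws its own AR parameter from the estimated sampling distribution so
    # the intervals also carry the AR-parameter uncertainty. The reported fit
    # keeps the plain Yule-Walker estimates.
    phi_full = base.phi_full
    target_sd = None
    phi_chol = None
    lag_idx = np.array(sorted(lags)) - 1 if lags else np.zeros(0, dtype=int)
    if lags and bias_adjust:
        phi_adj, sigma2_adj, phi_cov = reml_ar(dm.X, dm.y, lags)
        phi_full = np.zeros(max(lags))
        phi_full[lag_idx] = phi_adj
        target_sd = float(np.sqrt(max(sigma2_adj, 0.0)))
        try:
            phi_chol = np.linalg.cholesky(phi_cov)
        except np.linalg.LinAlgError:
            phi_chol = np.diag(np.sqrt(np.maximum(np.diag(phi_cov), 0.0)))
    p = len(phi_full)

    def _draw_gen_phi(rng) -> np.ndarray:
        """Generating AR parameters for one bootstrap world."""
        if phi_chol is None:
            return phi_full
        for _ in range(20):
            cand = phi_full[lag_idx] + phi_chol @ rng.standard_normal(len(lag_idx))
            full = np.zeros(p)
            full[lag_idx] = cand
            if _stationary_full(full, margin=1.02):
                return full
        return phi_full

    if scheme == "innovation":
        pool = _innovations(base.residuals, phi_full)
        if target_sd is not None and pool.std() > 0:
            pool = pool * (target_sd / pool.std())
        else:
            pool = pool * inflate
        draw_len = n + (_BOOT_BURNIN if p else 0)
    elif scheme == "moving_block":
        resid = base.residuals * inflate
        n_blocks = int(np.ceil(n / block_length))
        starts_max = n - block_length
        if starts_max < 0:
            raise DomainError("block_length exceeds series length")
    else:
        raise DomainError(f"unknown bootstrap scheme {scheme!r}")

    # post-window regressor rows, precomputed once: baseline (counterfactual)
    # and full (post-trend) versions; "observed" mode rebuilds actuals from
    # the resampled response instead
    post_months = dm.design.post_months()
    B_post = np.vstack([dm.baseline_row(m) for m in post_months])
    F_post = np.vstack([dm.full_row(m) for m in post_months])
    post_mask = dm.post_mask

    draws = np.empty(n_boot)
    failures = 0
    for b in range(n_boot):
        if scheme == "innovation":
            gen_phi = _draw_gen_phi(rng)
            idx = rng.integers(0, len(pool), size=draw_len)
            errors = _rebuild_errors(pool[idx], gen_phi, n)
        else:
            starts = rng.integers(0, starts_max + 1, size=n_blocks)
            errors = np.concatenate(
                [resid[s : s + block_length] for s in starts]
            )[:n]
        y_star = base.fitted + errors
        dm_star = dc_replace(dm, y=y_star)
        try:
            fit_star = fit_gls(dm_star, lags, diagnostics=False)
            expected = B_post @ fit_star.beta
            if np.any(expected <= 0):
                raise CounterfactualDomainError("non-positive counterfactual")
            actual = F_post @ fit_star.beta if mode == "fitted" else y_star[post_mask]
            draws[b] = np.mean(100.0 * (actual - expected) / expected)
        except ItsarError:
            draws[b] = np.nan
            failures += 1

    if failures > 0.05 * n_boot:
        raise BootstrapInstabilityError(
            f"{failures}/{n_boot} bootstrap refits failed "
            f"({100.0 * failures / n_boot:.1f}%)"
        )
    ok = draws[~np.isnan(draws)]
    ci_low, ci_high = np.percentile(ok, [2.5, 97.5], method="linear")

    return EffectEstimate(
        group_label=series.label,
        pct_change=point,
        ci_low=float(ci_low),
        ci_high=float(ci_high),
        n_boot=n_boot,
        seed=int(seed),
        per_month=per_month,
        draws=ok if keep_draws else None,
        n_failed=failures,
    )
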