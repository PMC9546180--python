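# Methods

## Model and design coding

The outcome is the monthly prescribing rate per 100 000 population. The
segmented design has four structural columns plus seasonal dummies:

| column | houses | coding |
|---|---|---|
| `intercept` | β₀, level at series start | 1 |
| `time` | β₁, baseline monthly change | months since the first window month (0-based) |
| `step` | β₂, level change at the advisory | 1 for months after the advisory |
| `post_trend` | β₃, monthly change post-advisory | months since the advisory for post months, 0 before |
| `month_02..month_12` | γ₂..γ₁₂ | month-of-year dummies, January reference |

Time is zeroed at the first included month so the intercept is the modeled
level at series start — a quantity analysts report directly — rather than a
mid-series value.

**Transition month.** The advisory month is excluded from the rows (exposure
within it is mixed) but keeps its place in the calendar: `time` jumps by 2
between the last pre month and the first post month. Exclusion removes an
observation, never a time increment.

**Post-trend origin.** By default the post-trend regressor is 1 in the first
modeled post month, so β₂ is the displacement at that month net of one month
of the new slope; with the transition month excluded this keeps β₂ and β₃
separately identified and matches reading the step coefficient as "change in
the advisory month". `StudyDesign(post_trend_start=0)` selects the
conventional alternative.

**Seasonal reference.** January, arbitrarily but fixed. Fitted values,
counterfactuals and effect estimates are invariant to the choice (test-pinned);
only the dummy coefficients change meaning.

## Estimation

1. **OLS** on the segmented design.
2. **Generalized Durbin–Watson** statistics d_j = Σ(e_t − e_{t−j})² / Σe_t²
   on the OLS residuals for lags 1..min(13, (n−1)/4).
3. **Stepwise AR order selection** (backward): lags 1..max_lag are fitted
   jointly by Yule–Walker; the lag with the largest p-value is dropped
   (ties: the higher lag) until all retained lags are significant. Each lag
   is tested against α/max_lag. The Bonferroni divisor is deliberate:
   backward elimination keeps, at each stage, the *most* significant of the
   candidate lags, so an unadjusted per-lag threshold would retain a spurious
   lag for white noise with probability ≈ 1 − (1−α)^13 ≈ 49%; with the
   adjustment the false-retention rate is ≈ α (measured ≈ 3% over 500
   simulations). `max_lag` defaults to 13 (monthly data may carry annual
   correlation) and is clamped below n/4.
4. **Yule–Walker** on the retained lags: sample autocovariances with divisor
   n (no demeaning — OLS residuals under an intercept already sum to zero),
   Toeplitz solve; subset-lag models solve the restricted moment equations.
   Nonstationary solutions are rejected with an error.
5. **Feasible GLS**: the response and design are whitened with the Cholesky
   factor of the exact stationary AR covariance (built from the extended
   Yule–Walker recursion), then refitted by OLS. The first p observations are
   scaled by the stationary covariance factor rather than dropped: at n = 35
   discarding rows is wasteful. Two-step (non-iterated), mirroring the
   classical Yule–Walker procedure. Standard errors and two-sided p-values
   use a t reference with df = n − k_regression − k_AR. With an empty lag set
   the fit reduces exactly to classical OLS.
6. **Total R²** = 1 − SSE/SST where SSE uses one-step-ahead predictions
   (structural fit plus the AR forecast of the error from whatever residual
   history exists) — the in-sample goodness-of-fit of the whole error model,
   not just the trend.

## Effect estimation

The counterfactual for each post month is the deterministic prediction with
`step` and `post_trend` forced to zero (baseline trend plus seasonal terms
extrapolated forward). The effect is the arithmetic mean over post months of
100 × (actual − expected)/expected. By default "actual" is the model-implied
post trend (a trend-versus-trend contrast, robust to single-month noise);
`mode="observed"` substitutes the raw observed rates. A non-positive
extrapolated baseline makes percentage change undefined and raises an error.

## Bootstrap confidence intervals

Percentile bootstrap, 5000 iterations by default, seeded and exactly
reproducible. Case resampling would destroy the time ordering an interrupted
time series requires, so the default scheme resamples *innovations*: the base
fit's structural residuals are whitened by the AR recursion, centred,
resampled with replacement, passed back through the AR filter (100-step
burn-in, so errors start near the stationary distribution), added to the base
deterministic fit, and the model is refitted with the AR order frozen at the
base selection. CI bounds are the 2.5th/97.5th empirical percentiles with
linear interpolation between order statistics. A moving-block alternative
(block length 3) is available via `scheme="moving_block"`. More than 5% of
refits failing aborts with an instability error.

**Error-generating process (the part that required care).** At n ≈ 35 with
trend, step and seasonal regressors, plain Yule–Walker estimates from the
detrended residuals are biased heavily toward zero — the projection absorbs
precisely the low-frequency error variation that autocorrelation lives in
(measured: mean φ̂ ≈ 0.26 when the generating φ = 0.5). A bootstrap that
rebuilds errors "with the fitted φ̂" therefore simulates a world with far
less autocorrelation than the data warrant and its CIs are ~25% too narrow
(measured coverage 80.5% for a nominal 95% interval). Two remedies are
combined, both switchable off via `bias_adjust=False`:

- the generating AR parameters and innovation variance come from **REML**
  (restricted maximum likelihood), which maximizes the likelihood of error
  contrasts and is therefore immune to the detrending bias (measured mean
  φ̂_REML ≈ 0.49 for true 0.5);
- each bootstrap iteration draws its generating φ from the REML estimate's
  approximate sampling distribution (normal, covariance from the curvature of
  the restricted log-likelihood, redrawn if nonstationary), because at this
  series length the AR parameter is estimated with an SD of ≈ 0.2 and a
  fixed-parameter bootstrap would ignore that uncertainty entirely.

With both in place the measured 95% CI coverage is ~94–95% and the
interaction test's type-I error ~3–5% under the study conditions. The
*reported* fit always keeps the plain Yule–Walker estimates; the adjustment
only shapes the resampling worlds. `itsar.ar.projection_adjusted_ar` provides
an independent moment-matching correction (matching expected residual
autocovariances under the projection) used to cross-check the bias story.

Interval endpoints, not the draws' SD, define the reported CI; the draws' SD
is exposed as `EffectEstimate.se` and feeds the interaction test (more
information than back-computing an SE from the CI width, which remains the
fallback for externally reported effects).

## Interaction test

For two independently estimated effects: difference E₁ − E₂, SE =
√(SE₁² + SE₂²), CI = difference ± 1.959964·SE, two-sided normal p-value. The
normal (not t) reference follows the method's published form. No multiplicity
adjustment is applied across subgroup comparisons.

## Synthetic data generator

`SimulationConfig` defaults encode the study conditions: window July 2009 –
June 2012 (24 pre months, July 2011 transition, 11 post months), level 182
and pre-slope −0.18 prescriptions per 100 000 (the published national
coefficient scale), advisory level change −13.1 and slope change −2.5, AR(1)
noise with φ = 0.5 and innovation SD 5 rate units, seasonal amplitude 10
units peak-to-trough (a smooth sinusoid anchored at zero in January, ~5% of
the level — typical mild prescribing seasonality), constant population
10⁶. The AR recursion burns in 100 steps so errors are stationary draws. The
generator attaches the analytic true effect
mean_t [100·(β₂ + β₃·k_t)/(β₀ + β₁·t + γ_m(t))] over post months, which the
pipeline reproduces exactly on noiseless configs (test-pinned to 1e−9).

Gaussian-on-rate noise is the default because the fitted model is linear on
the rate scale; `poisson-on-count` draws counts around the implied mean as a
robustness probe. Realized rates are floored at zero (rates are physically
non-negative); with the default parameters the floor is never reached.

What the generator does *not* emulate: prescriber switching dynamics to
substitute drugs, claims-processing lags between supply and recording dates,
population drift within groups, and advisory anticipation before the
transition month. Passing tests therefore demonstrate estimator correctness
under the model's assumptions, not robustness to those real-data features.

## Numerical choices and degenerate inputs

- Rates are validated against counts/populations to 1e−9 relative; panels
  must be gap-free (the first missing month is named in the error).
- Rank deficiency, nonstationary AR solutions, zero residual vectors
  (Durbin–Watson undefined) and df ≤ 0 raise typed errors rather than
  warnings.
- Windows need n_pre ≥ 3 and n_post ≥ 3 (slope identification); seasonal
  designs need enough months for full column rank (n_pre ≥ 13 with 11
  dummies is verified numerically in tests).
- Bootstrap seeds are mandatory; per-group seeds in multi-group runs are
  spawned from one root seed, so whole studies are byte-reproducible.
- Problem sizes in the test suite (500-replicate recovery and calibration
  runs, 200×1000 bootstrap coverage, 1000-run interaction calibration) were
  chosen to give Monte-Carlo error comfortably below the tested tolerances.

## Known limitations

- Exactly one interruption per analysis; no multiple-advisory designs.
- No maximum-likelihood AR estimation for the reported fit, no
  ARIMA/seasonal-ARIMA, no heteroscedasticity corrections, no BCa or
  studentized bootstrap, no small-sample bias correction of the percentage
  change itself.
- The percentage-change denominator is the extrapolated baseline; if the
  baseline trend crosses zero inside the post window the effect is undefined
  by construction.
- UK-style rate-only series are accepted (counts and denominators optional),
  but then aggregation across groups is unavailable.
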