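"""Estimate the advisory's effect with a bootstrap confidence interval.

The pre-advisory trend is extrapolated across the post window as the
counterfactual; the effect is the mean percentage difference between the
post-advisory trend and that baseline, with a 95% percentile CI from
resampling the fitted model's innovations.
"""

from itsar import MonthIndex, SimulationConfig, StudyDesign, bootstrap_ci, simulate_series

series, truth = simulate_series(SimulationConfig(), seed=7)
design = StudyDesign(advisory_month=MonthIndex(2011, 7))

effect = bootstrap_ci(series, design, n_boot=2000, seed=99)

print(f"mean % change: {effect.pct_change:+.1f}% "
      f"(95% CI {effect.ci_low:+.1f} to {effect.ci_high:+.1f}, "
      f"{effect.n_boot} bootstrap iterations)")
print(f"true generating effect: {truth['true_pct_change']:+.1f}%\n")

print("month     expected  modeled   % diff")
for month, expected, actual, pct in effect.per_month[:4]:
    print(f"{month}   {expected:7.1f}  {actual:7.1f}  {pct:+7.1f}%")
print("...")
print("'expected' is the no-advisory counterfactual rate per 100 000; "
      "'modeled' the fitted post-advisory trend; the headline effect is the "
      "mean of the monthly % differences.")
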