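"""Counterfactual extrapolation, percentage change, bootstrap CIs."""

import numpy as np
import pytest

from itsar import (
    MonthIndex,
    PrescriptionSeries,
    SimulationConfig,
    StudyDesign,
    bootstrap_ci,
    build_design,
    counterfactual,
    fit_gls,
    pct_change,
    simulate_series,
)
from itsar.errors import CounterfactualDomainError, DomainError

from conftest import JULY_2011, noiseless_series


def _fit(series, design, lags=frozenset()):
    return fit_gls(build_design(series, design), lags)


class TestCounterfactual:
    def test_flat_baseline_extrapolates_flat(self, plain_design):
        s, _, _ = noiseless_series((100.0, 0.0, -20.0, 0.0))
        expected = counterfactual(_fit(s, plain_design))
        np.testing.assert_allclose(expected, 100.0, atol=1e-9)

    def test_linear_trend_extrapolated_month_by_month(self):
        # post months sit at times 26..36 when 25 pre months precede the
        # advisory: expected = 200 - time, i.e. 174, 173, ..., 164
        s, _, _ = noiseless_series((200.0, -1.0, 0.0, 0.0), n_pre=25)
        d = StudyDesign(advisory_month=s.months[25], n_pre=25, n_post=11,
                        seasonal=False)
        expected = counterfactual(_fit(s, d))
        np.testing.assert_allclose(expected, 200.0 - np.arange(26, 37), atol=1e-9)

    def test_seasonal_dummy_carries_into_extrapolation(self):
        # advisory in June so the post window contains a July; the July
        # seasonal effect (+10 on a flat 100 baseline) must appear in the
        # counterfactual for that month
        gamma = np.zeros(12)
        gamma[6] = 10.0  # July
        s, _, _ = noiseless_series((100.0, 0.0, 0.0, 0.0), seasonal=gamma,
                                   start=MonthIndex(2009, 6))
        d = StudyDesign(advisory_month=MonthIndex(2011, 6))
        fit = _fit(s, d)
        expected = counterfactual(fit)
        months = d.post_months()
        july = months.index(MonthIndex(2011, 7))
        assert expected[july] == pytest.approx(110.0, abs=1e-8)
        others = np.delete(expected, july)
        np.testing.assert_allclose(others, 100.0, atol=1e-8)

    def test_nonpositive_baseline_rejected(self):
        # pre trend crosses zero inside the post window
        months = [MonthIndex(2009, 7) + k for k in range(36)]
        rates = np.maximum(5.0 - 0.2 * np.arange(36), 0.05)
        s = PrescriptionSeries(group_id={"group": "tiny"}, months=tuple(months),
                               rates=rates)
        d = StudyDesign(advisory_month=JULY_2011, seasonal=False)
        with pytest.raises(CounterfactualDomainError):
            counterfactual(_fit(s, d))


class TestPctChange:
    def test_constant_17pct_drop(self, plain_design):
        s, _, _ = noiseless_series((100.0, 0.0, -17.0, 0.0))
        fit = _fit(s, plain_design)
        assert pct_change(fit, mode="fitted") == pytest.approx(-17.0, abs=1e-9)
        assert pct_change(fit, mode="observed") == pytest.approx(-17.0, abs=1e-9)

    def test_symmetric_deviations_average_to_zero(self):
        # flat pre at 100; observed post alternates 110/90 (even count)
        start = MonthIndex(2009, 7)
        n_pre, n_post = 24, 10
        months = [start + k for k in range(n_pre + 1 + n_post)]
        rates = np.full(len(months), 100.0)
        rates[n_pre + 1:] = [110.0, 90.0] * (n_post // 2)
        s = PrescriptionSeries(group_id={"group": "x"}, months=tuple(months),
                               rates=rates)
        d = StudyDesign(advisory_month=start + n_pre, n_post=n_post,
                        seasonal=False)
        assert pct_change(_fit(s, d), mode="observed") == pytest.approx(0.0, abs=1e-9)

    def test_published_scale_coefficients(self, plain_design):
        """Level change -13.12 with slope change -2.53 on a flat baseline of
        182 averages to -100*(13.12 + 2.53*6)/182 over 11 post months."""
        s, _, _ = noiseless_series((182.0, 0.0, -13.12, -2.53))
        got = pct_change(_fit(s, plain_design))
        # independent hand evaluation, month by month
        oracle = np.mean([100.0 * (-13.12 - 2.53 * k) / 182.0
                          for k in range(1, 12)])
        assert got == pytest.approx(oracle, abs=1e-9)
        assert got == pytest.approx(-15.549450549450549, abs=1e-9)

    def test_bad_mode_rejected(self, plain_design):
        s, _, _ = noiseless_series((100.0, 0.0, -17.0, 0.0))
        with pytest.raises(DomainError):
            pct_change(_fit(s, plain_design), mode="banana")


class TestBootstrap:
    def test_noiseless_ci_collapses_to_point(self, plain_design):
        s, _, _ = noiseless_series((100.0, 0.0, -17.0, 0.0))
        eff = bootstrap_ci(s, plain_design, n_boot=200, seed=1, lags=frozenset())
        assert eff.pct_change == pytest.approx(-17.0, abs=1e-9)
        assert eff.ci_low == pytest.approx(-17.0, abs=1e-9)
        assert eff.ci_high == pytest.approx(-17.0, abs=1e-9)

    def test_seeded_determinism(self, plain_design):
        s, _ = simulate_series(SimulationConfig(seasonal=0.0), seed=8)
        a = bootstrap_ci(s, plain_design, n_boot=150, seed=99, lags={1})
        b = bootstrap_ci(s, plain_design, n_boot=150, seed=99, lags={1})
        assert (a.ci_low, a.ci_high) == (b.ci_low, b.ci_high)
        np.testing.assert_array_equal(a.draws, b.draws)
        c = bootstrap_ci(s, plain_design, n_boot=150, seed=100, lags={1})
        assert (a.ci_low, a.ci_high) != (c.ci_low, c.ci_high)

    def test_percentile_bounds_match_sort_and_interpolate_oracle(self, plain_design):
        s, _ = simulate_series(SimulationConfig(seasonal=0.0), seed=8)
        eff = bootstrap_ci(s, plain_design, n_boot=137, seed=5, lags={1})

        def quantile_oracle(draws, q):
            x = np.sort(draws)
            h = (len(x) - 1) * q
            lo = int(np.floor(h))
            hi = min(lo + 1, len(x) - 1)
            return x[lo] + (h - lo) * (x[hi] - x[lo])

        assert eff.ci_low == pytest.approx(quantile_oracle(eff.draws, 0.025), abs=1e-12)
        assert eff.ci_high == pytest.approx(quantile_oracle(eff.draws, 0.975), abs=1e-12)

    def test_per_month_records(self, plain_design):
        s, _, _ = noiseless_series((100.0, 0.0, -17.0, 0.0))
        eff = bootstrap_ci(s, plain_design, n_boot=100, seed=1, lags=frozenset())
        assert len(eff.per_month) == 11
        month, expected, actual, pct = eff.per_month[0]
        assert month == MonthIndex(2011, 8)
        assert expected == pytest.approx(100.0, abs=1e-9)
        assert pct == pytest.approx(-17.0, abs=1e-9)

    def test_moving_block_scheme_runs(self, plain_design):
        s, _ = simulate_series(SimulationConfig(seasonal=0.0), seed=8)
        eff = bootstrap_ci(s, plain_design, n_boot=150, seed=2, lags={1},
                           scheme="moving_block")
        assert np.isfinite(eff.ci_low) and eff.ci_low <= eff.ci_high

    def test_argument_validation(self, plain_design):
        s, _ = simulate_series(SimulationConfig(seasonal=0.0), seed=8)
        with pytest.raises(DomainError):
            bootstrap_ci(s, plain_design, n_boot=50, seed=1)
        with pytest.raises(DomainError):
            bootstrap_ci(s, plain_design, n_boot=200, seed=None)
        with pytest.raises(DomainError):
            bootstrap_ci(s, plain_design, n_boot=200, seed=1, scheme="cases")
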