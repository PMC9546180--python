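"""Segmented-regression design for an interrupted monthly time series.

The model for the rate :math:`y_t` (prescriptions per 100 000) is

.. math::

    y_t = \\beta_0 + \\beta_1\\,\\mathrm{time}_t + \\beta_2\\,\\mathrm{step}_t
          + \\beta_3\\,\\mathrm{posttrend}_t + \\sum_{m \\ne ref} \\gamma_m
          \\mathbb{1}[\\mathrm{month}(t)=m] + e_t,

where ``time`` counts calendar months since the first month of the study
window, ``step`` switches on after the advisory month, ``posttrend`` counts
calendar months since the advisory, and the :math:`\\gamma_m` are
month-of-year dummies. The advisory month itself is usually a *transition*
month: exposure within it is mixed, so its row is dropped from the fit while
calendar spacing of the time codes is preserved (exclusion removes a row,
never a time increment).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import CoverageError, DomainError, IdentifiabilityError
from .months import MonthIndex
from .timeseries import PrescriptionSeries

#: fixed column positions of the structural terms
IDX_INTERCEPT, IDX_TIME, IDX_STEP, IDX_POST_TREND = 0, 1, 2, 3


@dataclass(frozen=True)
class StudyDesign:
    """Window and coding choices for one interrupted time series analysis.

    Parameters
    ----------
    advisory_month : the intervention month (e.g. July 2011).
    n_pre : number of pre-advisory months modeled (>= 3).
    n_post : number of post-advisory months modeled (>= 3).
    transition_months : months excluded from the fit; defaults to the
        advisory month alone.
    seasonal : include 11 month-of-year dummies.
    seasonal_reference : calendar month (1-12) omitted as the dummy
        reference; January by default (arbitrary but fixed — predictions are
        invariant to the choice).
    post_trend_start : value of the post-trend regressor in the first
        post-advisory month. The default 1 makes the step coefficient the
        displacement at that month net of one month of new slope, keeping the
        level-change and slope-change terms separately identified when the
        advisory month is excluded; 0 is the conventional alternative.
    """

    advisory_month: MonthIndex
    n_pre: int = 24
    n_post: int = 11
    transition_months: frozenset[MonthIndex] = None  # type: ignore[assignment]
    seasonal: bool = True
    seasonal_reference: int = 1
    post_trend_start: int = 1

    def __post_init__(self) -> None:
        if self.transition_months is None:
            object.__setattr__(self, "transition_months",
                               frozenset({self.advisory_month}))
        else:
            object.__setattr__(self, "transition_months",
                               frozenset(self.transition_months))
        if self.n_pre < 3 or self.n_post < 3:
            raise DomainError("need at least 3 pre and 3 post months to identify slopes")
        if not 1 <= self.seasonal_reference <= 12:
            raise DomainError("seasonal_reference must be a calendar month 1..12")
        if self.post_trend_start not in (0, 1):
            raise DomainError("post_trend_start must be 0 or 1")
        bad = [m for m in self.transition_months
               if not (self.window_start <= m <= self.window_end)]
        if bad:
            raise DomainError(
                f"transition month(s) outside study window: "
                f"{[m.isoformat() for m in sorted(bad)]}"
            )

    @property
    def window_start(self) -> MonthIndex:
        return self.advisory_month - self.n_pre

    @property
    def window_end(self) -> MonthIndex:
        return self.advisory_month + self.n_post

    def window_months(self) -> list[MonthIndex]:
        """All calendar months of the window, including transition months."""
        n = self.n_pre + 1 + self.n_post
        return [self.window_start + k for k in range(n)]

    def post_months(self) -> list[MonthIndex]:
        """The post-advisory months (after the advisory, transition excluded)."""
        return [m for m in self.window_months()
                if m > self.advisory_month and m not in self.transition_months]


@dataclass(frozen=True)
class SegmentedDesignMatrix:
    """Design matrix and response for one series under one study design."""

    X: np.ndarray
    y: np.ndarray
    columns: tuple[str, ...]
    months: tuple[MonthIndex, ...]
    design: StudyDesign
    series_label: str = ""

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def k(self) -> int:
        return self.X.shape[1]

    @property
    def post_mask(self) -> np.ndarray:
        return self.X[:, IDX_STEP] > 0.5

    def seasonal_row(self, month: MonthIndex) -> np.ndarray:
        """Dummy coding of ``month``'s calendar month, matching the seasonal
        columns of ``X`` (empty when seasonality is off)."""
        d = self.design
        if not d.seasonal:
            return np.zeros(0)
        months_coded = [m for m in range(1, 13) if m != d.seasonal_reference]
        return np.array([1.0 if month.month == m else 0.0 for m in months_coded])

    def baseline_row(self, month: MonthIndex) -> np.ndarray:
        """Regressor row for ``month`` with step and post-trend forced to 0:
        the counterfactual (no-advisory) prediction basis."""
        t = month - self.design.window_start
        return np.concatenate([[1.0, float(t), 0.0, 0.0], self.seasonal_row(month)])

    def full_row(self, month: MonthIndex) -> np.ndarray:
        """Regressor row for ``month`` under the fitted (post-advisory) model."""
        d = self.design
        t = month - d.window_start
        if month > d.advisory_month:
            step = 1.0
            ptrend = float((month - d.advisory_month) - (1 - d.post_trend_start))
        else:
            step, ptrend = 0.0, 0.0
        return np.concatenate([[1.0, float(t), step, ptrend], self.seasonal_row(month)])

    def to_frame(self) -> pd.DataFrame:
        """Named design matrix plus response, for audit export."""
        df = pd.DataFrame(self.X, columns=list(self.columns))
        df.insert(0, "month", [m.isoformat() for m in self.months])
        df["response"] = self.y
        return df


def build_design(series: PrescriptionSeries, design: StudyDesign) -> SegmentedDesignMatrix:
    """Assemble the segmented design matrix for ``series`` under ``design``.

    Months outside the window are dropped; transition months are removed from
    the rows but keep their place in the calendar, so ``time`` and the
    post-trend regressor still count calendar months.

    Raises
    ------
    CoverageError
        The series does not span the study window.
    IdentifiabilityError
        All included rows fall on one side of the advisory.
    """
    if series.start > design.window_start or series.months[-1] < design.window_end:
        raise CoverageError(
            f"series {series.label!r} spans {series.start.isoformat()}.."
            f"{series.months[-1].isoformat()} but the window needs "
            f"{design.window_start.isoformat()}..{design.window_end.isoformat()}"
        )

    included = [m for m in design.window_months() if m not in design.transition_months]
    n_pre_rows = sum(1 for m in included if m <= design.advisory_month)
    n_post_rows = len(included) - n_pre_rows
    if n_pre_rows == 0 or n_post_rows == 0:
        raise IdentifiabilityError("window has no rows on one side of the advisory")

    columns = ["intercept", "time", "step", "post_trend"]
    if design.seasonal:
        columns += [f"month_{m:02d}" for m in range(1, 13) if m != design.seasonal_reference]

    # full_row handles the step/post-trend/seasonal coding per month
    proto = SegmentedDesignMatrix(
        X=np.zeros((0, len(columns))), y=np.zeros(0), columns=tuple(columns),
        months=(), design=design, series_label=series.label,
    )
    X = np.vstack([proto.full_row(m) for m in included])
    y = np.array([series.rates[series.index_of(m)] for m in included])

    return SegmentedDesignMatrix(
        X=X, y=y, columns=tuple(columns), months=tuple(included),
        design=design, series_label=series.label,
    )
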