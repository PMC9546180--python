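"""Monthly prescribing panels: reading, validation, rates, aggregation.

A *panel* is a delimited text file holding one row per (group, month) with a
prescription count and a population denominator (or a pre-computed rate).
Each distinct combination of group labels becomes one
:class:`PrescriptionSeries` whose months must be strictly consecutive.

The outcome unit throughout is prescriptions per 100 000 population per
month, the standard denominator of drug-utilisation research.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import DataError, DomainError, GapError, SchemaError
from .months import MonthIndex

logger = logging.getLogger(__name__)

PER_CAPITA_SCALE = 100_000.0
RATE_RTOL = 1e-9


@dataclass(frozen=True)
class PanelSchema:
    """Column-name mapping for a panel file.

    ``group`` lists the columns whose value combinations define the series
    (e.g. jurisdiction, sex, age band); any subset is valid. Either
    (``count``, ``population``) or ``rate`` columns must exist in the file.
    """

    month: str = "month"
    count: str = "prescriptions"
    population: str = "population"
    rate: str = "rate"
    group: tuple[str, ...] = ("group",)


def compute_rates(counts, populations) -> np.ndarray:
    """Prescriptions per 100 000 population, element-wise.

    Raises
    ------
    DomainError
        If lengths differ or any population is non-positive.
    """
    c = np.asarray(counts, dtype=float)
    p = np.asarray(populations, dtype=float)
    if c.shape != p.shape:
        raise DomainError(f"length mismatch: {c.shape} counts vs {p.shape} populations")
    if np.any(p <= 0):
        raise DomainError("populations must be strictly positive")
    if np.any(c < 0):
        raise DomainError("counts must be non-negative")
    return c / p * PER_CAPITA_SCALE


@dataclass(frozen=True)
class PrescriptionSeries:
    """A consecutive monthly series of prescribing for one group.

    Attributes
    ----------
    group_id : mapping of label-column name to value, e.g.
        ``{"country": "AU", "sex": "M"}``.
    months : ordered, strictly consecutive calendar months.
    counts : prescriptions per month, or None in rate-only mode.
    populations : persons per month, or None in rate-only mode.
    rates : prescriptions per 100 000 population per month.
    """

    group_id: Mapping[str, str]
    months: tuple[MonthIndex, ...]
    rates: np.ndarray
    counts: np.ndarray | None = None
    populations: np.ndarray | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "months", tuple(self.months))
        object.__setattr__(self, "rates", np.asarray(self.rates, dtype=float))
        if self.counts is not None:
            object.__setattr__(self, "counts", np.asarray(self.counts))
        if self.populations is not None:
            object.__setattr__(self, "populations", np.asarray(self.populations))
        self._validate()

    def _validate(self) -> None:
        n = len(self.months)
        if n == 0:
            raise DataError("empty series")
        for prev, cur in zip(self.months, self.months[1:]):
            if cur != prev.successor():
                raise GapError(
                    f"months not consecutive for group {self.label!r}: "
                    f"missing {prev.successor().isoformat()}"
                )
        for name, arr in (("rates", self.rates), ("counts", self.counts),
                          ("populations", self.populations)):
            if arr is not None and len(arr) != n:
                raise DataError(f"{name} has length {len(arr)}, expected {n}")
        if np.any(self.rates < 0):
            raise DataError("rates must be non-negative")
        if (self.counts is None) != (self.populations is None):
            raise DataError("counts and populations must be given together")
        if self.counts is not None:
            if np.any(np.asarray(self.populations, dtype=float) <= 0):
                raise DataError("populations must be strictly positive")
            implied = compute_rates(self.counts, self.populations)
            scale = np.maximum(np.abs(implied), 1.0)
            if np.any(np.abs(implied - self.rates) > RATE_RTOL * scale):
                raise DataError(
                    f"rates inconsistent with counts/populations for group "
                    f"{self.label!r}"
                )

    @property
    def label(self) -> str:
        """Human-readable group label, e.g. ``AU/M``."""
        return "/".join(str(v) for v in self.group_id.values()) or "all"

    def __len__(self) -> int:
        return len(self.months)

    @property
    def start(self) -> MonthIndex:
        return self.months[0]

    def index_of(self, month: MonthIndex) -> int:
        k = month - self.months[0]
        if not 0 <= k < len(self.months):
            raise DomainError(f"{month} outside series range")
        return k

    @classmethod
    def from_counts(
        cls,
        group_id: Mapping[str, str],
        months: Sequence[MonthIndex],
        counts,
        populations,
    ) -> "PrescriptionSeries":
        """Construct a series deriving rates from counts and populations."""
        rates = compute_rates(counts, populations)
        return cls(group_id=dict(group_id), months=tuple(months), rates=rates,
                   counts=counts, populations=populations)


def read_panel(path, schema: PanelSchema | None = None) -> list[PrescriptionSeries]:
    """Read a CSV panel into one series per distinct group-label combination.

    The file must have a header row; months are ISO ``YYYY-MM``. When both
    count and population columns are present, rates are derived; otherwise a
    rate column is required (rate-only mode, e.g. pre-aggregated national
    series).

    Raises
    ------
    SchemaError
        A required column is absent.
    DataError
        Duplicate (group, month) rows.
    GapError
        Non-consecutive months within a group, naming the first gap.
    """
    schema = schema or PanelSchema()
    path = Path(path)
    df = pd.read_csv(path, dtype=str)

    if schema.month not in df.columns:
        raise SchemaError(f"missing month column {schema.month!r} in {path.name}")
    group_cols = [g for g in schema.group if g in df.columns]
    missing_groups = set(schema.group) - set(group_cols)
    if missing_groups:
        raise SchemaError(f"missing group column(s) {sorted(missing_groups)} in {path.name}")

    has_counts = schema.count in df.columns and schema.population in df.columns
    has_rate = schema.rate in df.columns
    if not has_counts and not has_rate:
        raise SchemaError(
            f"need either ({schema.count!r}, {schema.population!r}) or "
            f"{schema.rate!r} columns in {path.name}"
        )

    known = {schema.month, schema.count, schema.population, schema.rate, *schema.group}
    extra = [c for c in df.columns if c not in known]
    if extra:
        logger.warning("ignoring unmapped columns %s in %s", extra, path.name)

    df["_month"] = df[schema.month].map(MonthIndex.parse)

    out: list[PrescriptionSeries] = []
    grouped = df.groupby(group_cols, sort=True) if group_cols else [((), df)]
    for key, sub in grouped:
        if not isinstance(key, tuple):
            key = (key,)
        gid = dict(zip(group_cols, (str(k) for k in key)))
        sub = sub.sort_values("_month", key=lambda s: s.map(lambda m: (m.year, m.month)))
        months = list(sub["_month"])
        dup = [m for m, c in pd.Series([m.isoformat() for m in months]).value_counts().items() if c > 1]
        if dup:
            raise DataError(f"duplicate rows for group {gid} at month(s) {sorted(dup)}")
        for prev, cur in zip(months, months[1:]):
            if cur != prev.successor():
                raise GapError(
                    f"non-consecutive months for group {gid}: "
                    f"missing {prev.successor().isoformat()}"
                )
        if has_counts and sub[schema.count].notna().all() and sub[schema.population].notna().all():
            counts = sub[schema.count].astype(float).to_numpy()
            pops = sub[schema.population].astype(float).to_numpy()
            out.append(PrescriptionSeries.from_counts(gid, months, counts, pops))
        elif has_rate and sub[schema.rate].notna().all():
            rates = sub[schema.rate].astype(float).to_numpy()
            out.append(PrescriptionSeries(group_id=gid, months=tuple(months), rates=rates))
        else:
            raise DataError(
                f"group {gid}: missing values in count/population and no complete rate column"
            )
    return out


def write_panel(series: Sequence[PrescriptionSeries], path,
                schema: PanelSchema | None = None) -> Path:
    """Write series back to a CSV panel readable by :func:`read_panel`."""
    schema = schema or PanelSchema()
    path = Path(path)
    frames = []
    for s in series:
        d = {schema.month: [m.isoformat() for m in s.months]}
        for col, val in s.group_id.items():
            d[col] = val
        if s.counts is not None:
            d[schema.count] = np.asarray(s.counts)
            d[schema.population] = np.asarray(s.populations)
        d[schema.rate] = np.round(s.rates, 12)
        frames.append(pd.DataFrame(d))
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)
    return path


def aggregate_series(series: Sequence[PrescriptionSeries],
                     group_id: Mapping[str, str]) -> PrescriptionSeries:
    """Pool subgroup series sharing the same months by summing counts and
    populations; the pooled rate is then the population-weighted mean of the
    subgroup rates."""
    if not series:
        raise DataError("nothing to aggregate")
    months = series[0].months
    for s in series[1:]:
        if s.months != months:
            raise DataError("aggregation requires identical month ranges")
    if any(s.counts is None for s in series):
        raise DataError("aggregation requires counts and populations")
    counts = np.sum([np.asarray(s.counts, dtype=float) for s in series], axis=0)
    pops = np.sum([np.asarray(s.populations, dtype=float) for s in series], axis=0)
    return PrescriptionSeries.from_counts(dict(group_id), months, counts, pops)


def write_results_table(rows: Sequence[Mapping], path) -> Path:
    """Write a list of result records (dicts) as a CSV table.

    Used for coefficient tables (group, term, estimate, SE, p-value) and for
    effect/interaction summaries; column order follows the first record.
    """
    path = Path(path)
    pd.DataFrame(list(rows)).to_csv(path, index=False, float_format="%.10g")
    return path
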