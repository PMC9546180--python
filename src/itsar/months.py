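"""Calendar-month index for monthly panels.

The study design is strictly monthly, so months are represented as an explicit
``(year, month)`` pair rather than a timestamp: there is no day-of-month to be
ambiguous about, and month arithmetic (successor, differences) is exact
integer arithmetic.
"""

from __future__ import annotations

import functools
import re
from dataclasses import dataclass

from .errors import DomainError

_ISO_MONTH = re.compile(r"^(\d{4})-(\d{2})$")


@functools.total_ordering
@dataclass(frozen=True)
class MonthIndex:
    """A calendar month, ordered by ``(year, month)``.

    Parameters
    ----------
    year : int
        Calendar year.
    month : int
        Calendar month, 1-12.
    """

    year: int
    month: int

    def __post_init__(self) -> None:
        if not 1 <= self.month <= 12:
            raise DomainError(f"month must be in 1..12, got {self.month}")

    # -- ordering ---------------------------------------------------------
    def __lt__(self, other: "MonthIndex") -> bool:
        return (self.year, self.month) < (other.year, other.month)

    # -- arithmetic -------------------------------------------------------
    def _ordinal(self) -> int:
        return self.year * 12 + (self.month - 1)

    @classmethod
    def _from_ordinal(cls, n: int) -> "MonthIndex":
        return cls(n // 12, n % 12 + 1)

    def __add__(self, k: int) -> "MonthIndex":
        """The month ``k`` calendar months later (``k`` may be negative)."""
        return MonthIndex._from_ordinal(self._ordinal() + int(k))

    def __sub__(self, other):
        """Difference in months if ``other`` is a MonthIndex, else shift."""
        if isinstance(other, MonthIndex):
            return self._ordinal() - other._ordinal()
        return self + (-int(other))

    def successor(self) -> "MonthIndex":
        """The next calendar month, with year rollover."""
        return self + 1

    # -- formatting -------------------------------------------------------
    @classmethod
    def parse(cls, text: str) -> "MonthIndex":
        """Parse an ISO ``YYYY-MM`` string."""
        m = _ISO_MONTH.match(str(text).strip())
        if m is None:
            raise DomainError(f"not an ISO YYYY-MM month: {text!r}")
        return cls(int(m.group(1)), int(m.group(2)))

    def isoformat(self) -> str:
        return f"{self.year:04d}-{self.month:02d}"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.isoformat()


def month_range(start: MonthIndex, n: int) -> list[MonthIndex]:
    """``n`` consecutive months beginning at ``start``."""
    if n < 0:
        raise DomainError("n must be non-negative")
    return [start + k for k in range(n)]
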