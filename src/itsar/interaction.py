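"""Between-group comparison of effect estimates (test for interaction).

Two independently estimated percentage changes are compared by the standard
normal-theory test for interaction: the difference of the estimates, its
standard error as the root-sum-square of the group standard errors, a 95% CI,
and a two-sided z test. When a group's SE is not reported directly it can be
recovered from a 95% CI via its width.
"""

from __future__ import annotations

from dataclasses import dataclass

from scipy import stats

from .effects import EffectEstimate
from .errors import DomainError

__all__ = ["InteractionResult", "se_from_ci", "interaction_test", "compare_effects"]

#: two-sided 95% normal critical value
Z95 = 1.959964


@dataclass(frozen=True)
class InteractionResult:
    """Difference between two group effects (percentage points)."""

    difference: float
    se_diff: float
    ci_low: float
    ci_high: float
    z: float
    p_value: float
    label_1: str = ""
    label_2: str = ""

    def to_record(self) -> dict:
        return {
            "group_1": self.label_1,
            "group_2": self.label_2,
            "difference": self.difference,
            "se_diff": self.se_diff,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "z": self.z,
            "p_value": self.p_value,
        }


def se_from_ci(ci_low: float, ci_high: float) -> float:
    """Standard error implied by a 95% confidence interval's width,
    ``(high - low) / (2 * 1.959964)``."""
    if not ci_high > ci_low:
        raise DomainError(f"inverted CI bounds ({ci_low}, {ci_high})")
    return (ci_high - ci_low) / (2.0 * Z95)


def interaction_test(e1: float, se1: float, e2: float, se2: float,
                     label_1: str = "", label_2: str = "") -> InteractionResult:
    """Test whether two effect estimates differ.

    ``difference = e1 - e2``, ``se_diff = sqrt(se1^2 + se2^2)``; the CI is
    ``difference +/- 1.959964 * se_diff`` and the p-value is the two-sided
    normal tail probability of ``difference / se_diff``.
    """
    if not (se1 > 0 and se2 > 0):
        raise DomainError("standard errors must be positive")
    diff = e1 - e2
    se_diff = (se1 ** 2 + se2 ** 2) ** 0.5
    z = diff / se_diff
    p = 2.0 * stats.norm.sf(abs(z))
    return InteractionResult(
        difference=diff, se_diff=se_diff,
        ci_low=diff - Z95 * se_diff, ci_high=diff + Z95 * se_diff,
        z=z, p_value=float(p), label_1=label_1, label_2=label_2,
    )


def compare_effects(a: EffectEstimate, b: EffectEstimate) -> InteractionResult:
    """Interaction test between two bootstrap effect estimates.

    SEs are taken from the bootstrap draws' standard deviation when draws are
    stored (more information than the CI width); otherwise they are recovered
    from the percentile CI via :func:`se_from_ci`.
    """
    def _se(e: EffectEstimate) -> float:
        s = e.se
        if s != s or s <= 0:  # NaN or degenerate: fall back to the CI width
            return se_from_ci(e.ci_low, e.ci_high)
        return s

    return interaction_test(a.pct_change, _se(a), b.pct_change, _se(b),
                            label_1=a.group_label, label_2=b.group_label)
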