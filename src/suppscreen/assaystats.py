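"""Survival-assay statistics: relative survival and the unpaired t-test.

Relative survival normalizes each strain's percent survival to the matched
control strain measured the same day.  Group comparisons use the classical
equal-variance (Student's) two-sample t-test, two-sided, with the screen's
significance tiers: ``*`` for p < 0.05 and ``**`` for p < 0.005 (as printed
in the figure legends, not the conventional 0.01).
"""

from __future__ import annotations

import math
from typing import Sequence

import numpy as np
from scipy import stats

__all__ = ["relative_survival", "significance_tier", "unpaired_t_test"]


def relative_survival(strain_percent: float, control_percent: float) -> float:
    """Percent survival of a strain relative to its same-day control.

    ``100 × strain / control``; a zero control is undefined and raises.
    """
    if strain_percent < 0 or control_percent < 0:
        raise ValueError("percent survival must be non-negative")
    if control_percent == 0:
        raise ValueError("relative survival undefined for a control at 0% survival")
    return 100.0 * strain_percent / control_percent


def unpaired_t_test(group_a: Sequence[float],
                    group_b: Sequence[float]) -> tuple[float, float]:
    """Student's unpaired two-sample t-test (equal variance, two-sided).

    Returns ``(t, p)`` with df = n_a + n_b − 2.  Degenerate zero-variance
    inputs use the convention p = 1 for equal means and p = 0 (t = ±inf)
    for unequal means.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 observations")
    pooled = ((len(a) - 1) * a.var(ddof=1) + (len(b) - 1) * b.var(ddof=1))
    if pooled == 0.0:
        if a.mean() == b.mean():
            return 0.0, 1.0
        return math.copysign(math.inf, a.mean() - b.mean()), 0.0
    t, p = stats.ttest_ind(a, b, equal_var=True)
    return float(t), float(p)


def significance_tier(p: float) -> str:
    """Figure-legend significance label: '**' p<0.005, '*' p<0.05, else 'ns'."""
    if p < 0.005:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"
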