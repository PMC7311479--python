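"""Shared statistics: the unpaired two-sample t-test and quadrature propagation."""

from __future__ import annotations

import math
from typing import NamedTuple, Sequence

import numpy as np
from scipy import stats as _scipy_stats

__all__ = ["TTestResult", "unpaired_t_test", "propagate_quadrature"]


class TTestResult(NamedTuple):
    t: float
    df: float
    p: float


def unpaired_t_test(
    group_a: Sequence[float],
    group_b: Sequence[float],
    equal_var: bool = True,
) -> TTestResult:
    """Unpaired two-sample t-test (two-sided).

    Default is the classic equal-variance Student's test with
    df = nA + nB - 2; ``equal_var=False`` switches to Welch's test.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs n >= 2")
    res = _scipy_stats.ttest_ind(a, b, equal_var=equal_var)
    df = a.size + b.size - 2 if equal_var else float(res.df)
    return TTestResult(t=float(res.statistic), df=float(df), p=float(res.pvalue))


def propagate_quadrature(e1: float, e2: float) -> float:
    """Standard error of a difference of independent estimates: sqrt(e1^2 + e2^2)."""
    if e1 < 0 or e2 < 0:
        raise ValueError("errors must be non-negative")
    return math.hypot(e1, e2)
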