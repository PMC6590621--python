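"""Shared statistical primitives: unpaired Student's t-test and Benjamini-Hochberg.

The t-test is the classical pooled-variance form (Welch available behind a flag);
p-values are two-sided.  Degenerate inputs (both groups constant) are resolved by
rule rather than returning NaN: equal constants give t=0, p=1; unequal constants
give p=0 with ``degenerate=True``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests


@dataclass
class GroupComparison:
    t: float
    df: float
    p: float
    mean_a: float
    mean_b: float
    n_a: int
    n_b: int
    degenerate: bool = False


def t_test_unpaired(x, y, *, welch: bool = False) -> GroupComparison:
    """Two-sided unpaired t-test of ``x`` vs ``y`` (statistic sign: mean(x) - mean(y))."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("need at least 2 observations per group")
    mean_a, mean_b = float(x.mean()), float(y.mean())
    n_a, n_b = int(x.size), int(y.size)
    if x.var(ddof=1) == 0.0 and y.var(ddof=1) == 0.0:
        if mean_a == mean_b:
            return GroupComparison(0.0, n_a + n_b - 2, 1.0, mean_a, mean_b, n_a, n_b)
        return GroupComparison(
            np.inf if mean_a > mean_b else -np.inf,
            n_a + n_b - 2, 0.0, mean_a, mean_b, n_a, n_b, degenerate=True,
        )
    res = sps.ttest_ind(x, y, equal_var=not welch)
    df = float(res.df) if welch else n_a + n_b - 2
    return GroupComparison(
        float(res.statistic), df, float(res.pvalue), mean_a, mean_b, n_a, n_b
    )


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment, order-preserving, clipped at 1."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]
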