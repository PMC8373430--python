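"""Shared hypothesis-testing primitives used by the differential and classify layers."""

from __future__ import annotations

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests


def bh_adjust(p) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (monotone, clipped at 1)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return np.empty(0, dtype=float)
    if np.any(~np.isfinite(p)) or np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def rank_sum_test(x, y, *, exact_max_n: int = 10) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum (Mann–Whitney) test.

    Uses exact null enumeration when both groups have at most ``exact_max_n``
    observations and the pooled data carry no ties; otherwise the normal
    approximation with tie correction.  When every pooled value is identical
    the test is degenerate and p = 1 by convention.

    Returns ``(U statistic of the first sample, p-value)``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        return float(x.size * y.size / 2.0), 1.0
    ties = np.unique(pooled).size < pooled.size
    method = "exact" if (x.size <= exact_max_n and y.size <= exact_max_n and not ties) else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(min(res.pvalue, 1.0))
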