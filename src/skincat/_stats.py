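"""Shared statistical helpers."""

from __future__ import annotations

import numpy as np
from scipy import stats


def rank_sum_test(x, y, alternative: str = "two-sided") -> tuple[float, float]:
    """Two-sample Wilcoxon rank-sum (Mann-Whitney U) test.

    Uses the exact null distribution when both groups have n <= 25 and no
    ties are present, otherwise the normal approximation with continuity
    correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("rank_sum_test requires non-empty groups")
    pooled = np.concatenate([x, y])
    has_ties = len(np.unique(pooled)) < len(pooled)
    method = "exact" if (len(x) <= 25 and len(y) <= 25 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative=alternative, method=method)
    return float(res.statistic), float(res.pvalue)


def u_statistic(x, y) -> float:
    """Mann-Whitney U of x versus y (midranks for ties), without a p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ranks = stats.rankdata(np.concatenate([x, y]))
    return float(ranks[: len(x)].sum() - len(x) * (len(x) + 1) / 2.0)


def bonferroni(pvalues) -> np.ndarray:
    """Bonferroni adjustment, clipped at 1."""
    p = np.asarray(pvalues, dtype=float)
    return np.minimum(p * len(p), 1.0)
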