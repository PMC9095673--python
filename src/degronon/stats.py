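"""Shared statistical tests.

All between-group significance tests in the pipeline use the two-sided
Mann-Whitney U test; correlations are Spearman rank correlations.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
from scipy import stats


def two_group_test(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test.

    Uses the exact null distribution for small samples (both groups <= 8,
    no ties) and the normal approximation with tie correction otherwise.
    Returns ``(U, p_two_sided)`` where U is the statistic for the first group.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("two_group_test requires non-empty groups")
    pooled = np.concatenate([x, y])
    has_ties = np.unique(pooled).size < pooled.size
    if x.size <= 8 and y.size <= 8 and not has_ties:
        method = "exact"
    else:
        method = "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def spearman(x: Sequence[float], y: Sequence[float]) -> tuple[float, float, int]:
    """Spearman correlation with average ranks for ties.

    Returns ``(r, p, n)``; ``(nan, nan, n)`` when n < 3, where the
    correlation is undefined for our purposes.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = int(x.size)
    if n < 3:
        return float("nan"), float("nan"), n
    res = stats.spearmanr(x, y)
    return float(res.statistic), float(res.pvalue), n
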