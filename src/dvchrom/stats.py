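"""Shared statistics: Wilcoxon rank-sum wrapper and Simes combination."""

from __future__ import annotations

from itertools import combinations

import numpy as np
from scipy import stats as sps

__all__ = ["rank_sum_test", "simes"]


def _exact_rank_sum_p(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided exact permutation p for the rank-sum statistic (midranks,
    so ties are handled); counts |W - E[W]| >= observed over all splits."""
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)
    n = len(x)
    w_obs = ranks[:n].sum()
    e_w = n * (len(pooled) + 1) / 2.0
    dev = abs(w_obs - e_w)
    count = total = 0
    for combo in combinations(range(len(pooled)), n):
        w = ranks[list(combo)].sum()
        total += 1
        if abs(w - e_w) >= dev - 1e-12:
            count += 1
    return count / total


def rank_sum_test(x, y) -> float:
    """Two-sided Wilcoxon rank-sum p-value.

    Exact permutation when both samples have at most 10 observations,
    otherwise the normal approximation with tie correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        return float("nan")
    if len(x) <= 10 and len(y) <= 10:
        return _exact_rank_sum_p(x, y)
    return float(
        sps.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic").pvalue
    )


def simes(pvalues) -> float:
    """Simes' combined p-value: min_i (n * p_(i) / i)."""
    p = np.sort(np.asarray(pvalues, dtype=float))
    n = len(p)
    if n == 0:
        return float("nan")
    return float(min(1.0, (n * p / np.arange(1, n + 1)).min()))
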