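"""Exact small-table statistics shared across the package.

The Fisher exact test here is an exact integer implementation: all
hypergeometric probabilities for a 2x2 table share the denominator
C(N, c1), so tail and two-sided sums reduce to integer comparisons and
integer sums, avoiding any floating-point tie ambiguity.  This matters
because the two-sided p-value includes every table whose probability is
<= the observed table's, and near-ties decided in floats can flip the
inclusion of a whole term.
"""

from __future__ import annotations

from fractions import Fraction
from math import comb

import numpy as np
from scipy import stats as _scipy_stats
from statsmodels.stats.multitest import multipletests

__all__ = ["fisher_exact_2x2", "bh_adjust", "rank_sum_test"]


def _table_margins(table):
    (a, b), (c, d) = table
    for x in (a, b, c, d):
        if x < 0 or int(x) != x:
            raise ValueError(f"2x2 table entries must be non-negative integers, got {table!r}")
    return int(a), int(b), int(c), int(d)


_EXACT_N_LIMIT = 10_000  # beyond this the big-integer enumeration is wasteful


def fisher_exact_2x2(table, alternative: str = "two-sided") -> float:
    """Fisher exact p-value for a 2x2 table ``[[a, b], [c, d]]``.

    alternative: 'two-sided', 'greater' (enrichment of the a-cell), or
    'less'.  Conditioning is on all margins; probabilities are computed
    as exact integers over the common denominator C(N, a+c).  Very large
    tables (N > 10,000, e.g. sequence-opportunity margins) fall back to
    the floating hypergeometric evaluation, whose error is far below any
    meaningful digit at that size.
    """
    a, b, c, d = _table_margins(table)
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    if n == 0:
        return 1.0
    if n > _EXACT_N_LIMIT:
        alt = {"two-sided": "two-sided", "greater": "greater", "less": "less"}[alternative]
        return float(_scipy_stats.fisher_exact([[a, b], [c, d]], alternative=alt)[1])
    k_min = max(0, c1 - r2)
    k_max = min(c1, r1)
    # integer numerators of the hypergeometric pmf, common denominator C(n, c1)
    nums = {k: comb(r1, k) * comb(r2, c1 - k) for k in range(k_min, k_max + 1)}
    denom = comb(n, c1)
    if alternative == "greater":
        s = sum(v for k, v in nums.items() if k >= a)
    elif alternative == "less":
        s = sum(v for k, v in nums.items() if k <= a)
    elif alternative == "two-sided":
        obs = nums[a]
        s = sum(v for v in nums.values() if v <= obs)
    else:
        raise ValueError(f"unknown alternative {alternative!r}")
    return float(Fraction(s, denom))


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted values, in input order."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return np.empty(0, dtype=float)
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def rank_sum_test(x, y, alternative: str = "less", exact_max_n: int = 12) -> float:
    """Wilcoxon rank-sum (Mann-Whitney) p-value for group ``x`` vs ``y``.

    Exact null distribution when both groups have <= ``exact_max_n``
    observations and there are no ties; otherwise the normal
    approximation with continuity and tie correction.  Two degenerate
    constant groups give p = 1 by convention (mid-rank ties carry no
    ordering information).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if alternative not in ("less", "greater", "two-sided"):
        raise ValueError(f"unknown alternative {alternative!r}")
    if x.size < 2 or y.size < 2:
        raise ValueError("each group needs at least two observations")
    pooled = np.concatenate([x, y])
    has_ties = np.unique(pooled).size < pooled.size
    if np.ptp(pooled) == 0:
        return 1.0
    if not has_ties and x.size <= exact_max_n and y.size <= exact_max_n:
        method = "exact"
    else:
        method = "asymptotic"
    res = _scipy_stats.mannwhitneyu(
        x, y, alternative=alternative, method=method, use_continuity=True
    )
    return float(res.pvalue)
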