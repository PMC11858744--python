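"""Rank-based per-subject robustness checks.

Mann-Whitney U between two cohorts' per-subject percentage tables, and the
Wilcoxon signed-rank test of one cohort against a fixed baseline (50% for an
unbiased 2AFC task).  Both report a tie-corrected normal approximation by
default and switch to exact enumeration for small samples, where enumeration
is cheap (all C(n1+n2, n1) group assignments, resp. all 2^n sign patterns).

Conventions, since they vary across software: the U of the first-named
sample is reported (its complement n1*n2 - U is included), and Wilcoxon drops
zero differences and reports the smaller signed-rank sum.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np
from scipy.stats import norm, rankdata

from .data import ValidationError

#: largest number of group assignments C(n1+n2, n1) enumerated under
#: method="auto" (8 vs 8 gives 12870; the count, not n1*n2, is what bounds
#: the work, so the cutoff is on the enumeration size directly)
_EXACT_U_LIMIT = 20000
#: largest n for exact Wilcoxon sign-flip enumeration under method="auto"
_EXACT_W_LIMIT = 15


@dataclass(frozen=True)
class RankTestResult:
    statistic: float
    statistic_complement: float
    mean_difference: float
    p_value: float
    method: str
    n1: int
    n2: int


def _u_from_positions(ranks: np.ndarray, positions: tuple[int, ...], n1: int) -> float:
    return float(ranks[list(positions)].sum() - n1 * (n1 + 1) / 2.0)


def mann_whitney_u(
    group_x: np.ndarray, group_y: np.ndarray, method: str = "auto"
) -> RankTestResult:
    """Mann-Whitney U test with midrank tie handling.

    ``statistic`` is U of ``group_x``; ``statistic_complement`` is
    n1*n2 - U.  ``method`` is "auto", "normal" or "exact"; "auto" uses exact
    enumeration when n1*n2 <= 400.
    """
    x = np.asarray(group_x, dtype=float)
    y = np.asarray(group_y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValidationError("both groups must be non-empty")
    n1, n2 = x.size, y.size
    pooled = np.concatenate([x, y])
    ranks = rankdata(pooled)
    u_x = float(ranks[:n1].sum() - n1 * (n1 + 1) / 2.0)
    u_y = n1 * n2 - u_x
    use_exact = method == "exact" or (
        method == "auto" and comb(n1 + n2, n1) <= _EXACT_U_LIMIT
    )
    if use_exact:
        total = 0
        extreme_lo = 0
        extreme_hi = 0
        for pos in combinations(range(n1 + n2), n1):
            u = _u_from_positions(ranks, pos, n1)
            total += 1
            if u <= u_x:
                extreme_lo += 1
            if u >= u_x:
                extreme_hi += 1
        p = min(1.0, 2.0 * min(extreme_lo / total, extreme_hi / total))
        used = "exact"
    else:
        mu = n1 * n2 / 2.0
        n = n1 + n2
        _, counts = np.unique(pooled, return_counts=True)
        tie_term = float(np.sum(counts**3 - counts))
        var = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
        if var <= 0:
            p = 1.0
        else:
            # continuity correction toward the mean
            z = (u_x - mu - 0.5 * np.sign(u_x - mu)) / np.sqrt(var)
            p = float(2.0 * norm.sf(abs(z)))
            p = min(1.0, p)
        used = "normal"
    return RankTestResult(
        statistic=u_x,
        statistic_complement=u_y,
        mean_difference=float(x.mean() - y.mean()),
        p_value=p,
        method=f"mann_whitney_u:{used}",
        n1=n1,
        n2=n2,
    )


def wilcoxon_signed_rank(
    values: np.ndarray, baseline: float = 50.0, method: str = "auto"
) -> RankTestResult:
    """Wilcoxon signed-rank test of ``values`` against a fixed baseline.

    Zero differences are dropped; ties get midranks; ``statistic`` is the
    smaller of the positive/negative rank sums, ``statistic_complement`` the
    larger.  "auto" enumerates all sign patterns exactly when n <= 15.
    """
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValidationError("values must be non-empty")
    d = v - baseline
    d = d[d != 0]
    if d.size == 0:
        raise ValidationError("all values equal the baseline; test undefined")
    n = d.size
    ranks = rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    w_minus = float(ranks[d < 0].sum())
    w = min(w_plus, w_minus)
    use_exact = method == "exact" or (method == "auto" and n <= _EXACT_W_LIMIT)
    if use_exact:
        total = 2**n
        lo = 0
        hi = 0
        for mask in range(total):
            signs = np.array([(mask >> i) & 1 for i in range(n)], dtype=bool)
            wp = float(ranks[signs].sum())
            if wp <= w_plus:
                lo += 1
            if wp >= w_plus:
                hi += 1
        p = min(1.0, 2.0 * min(lo / total, hi / total))
        used = "exact"
    else:
        mu = n * (n + 1) / 4.0
        _, counts = np.unique(np.abs(d), return_counts=True)
        tie_term = float(np.sum(counts**3 - counts))
        var = n * (n + 1) * (2 * n + 1) / 24.0 - tie_term / 48.0
        if var <= 0:
            p = 1.0
        else:
            z = (w_plus - mu - 0.5 * np.sign(w_plus - mu)) / np.sqrt(var)
            p = float(2.0 * norm.sf(abs(z)))
            p = min(1.0, p)
        used = "normal"
    return RankTestResult(
        statistic=w,
        statistic_complement=max(w_plus, w_minus),
        mean_difference=float(v.mean() - baseline),
        p_value=p,
        method=f"wilcoxon_signed_rank:{used}",
        n1=n,
        n2=0,
    )
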