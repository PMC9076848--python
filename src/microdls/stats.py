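"""Cohort-level statistical comparisons.

The paired comparisons mirror the study's analysis plan: Wilcoxon signed-rank
for stable-versus-deceleration relHI summaries, Wilcoxon rank-sum for group
contrasts (PDA, phototherapy), and paired t-tests with Bonferroni correction
(significance at p < 0.05 / 10 = 0.005) for the ten measurement-location
pairs.

The Wilcoxon tests are implemented here rather than delegated because the
exact small-sample paths must handle mid-ranks for ties: the signed-rank
null distribution is built by dynamic programming over the 2^n sign
assignments (on the doubled-rank integer grid), the rank-sum distribution by
counting rank subsets.  Large samples switch to the normal approximation
with the usual tie corrections.  All p-values are two-sided.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy import stats as sstats

__all__ = [
    "TestResult",
    "LocationComparison",
    "wilcoxon_signed_rank",
    "wilcoxon_rank_sum",
    "pairwise_location_ttests",
]


@dataclass
class TestResult:
    statistic: float
    p: float
    n: int
    method: str

    def __post_init__(self) -> None:
        if not (0.0 <= self.p <= 1.0):
            raise ValueError("p must lie in [0, 1]")


@dataclass
class LocationComparison:
    pair: tuple[str, str]
    mean_diff: float
    statistic: float
    p: float
    n: int
    significant: bool
    threshold: float
    note: str = ""


def _midranks(x: np.ndarray) -> np.ndarray:
    return sstats.rankdata(x, method="average")


def _two_sided_from_pmf(grid_p: np.ndarray, idx: int) -> float:
    """Two-sided p = 2*min(P(T<=t), P(T>=t)) capped at 1, from an exact pmf."""
    cdf = grid_p[: idx + 1].sum()
    sf = grid_p[idx:].sum()
    return float(min(1.0, 2.0 * min(cdf, sf)))


def wilcoxon_signed_rank(x, y=None, exact_max_n: int = 25) -> TestResult:
    """Two-sided Wilcoxon signed-rank test.

    Zero differences are dropped; tied absolute differences get mid-ranks.
    For n <= `exact_max_n` the null distribution of W+ is computed exactly
    (dynamic programming over sign assignments on doubled ranks); larger
    samples use the normal approximation with tie correction.
    """
    x = np.asarray(x, dtype=float)
    d = x if y is None else x - np.asarray(y, dtype=float)
    d = d[np.isfinite(d)]
    d = d[d != 0]
    n = d.size
    if n == 0:
        return TestResult(statistic=0.0, p=1.0, n=0, method="signed-rank degenerate")
    r = _midranks(np.abs(d))
    w_plus = float(r[d > 0].sum())
    if n <= exact_max_n:
        # doubled mid-ranks are integers; DP over the 2^n equally likely signs
        r2 = np.rint(2 * r).astype(np.int64)
        total = int(r2.sum())
        pmf = np.zeros(total + 1)
        pmf[0] = 1.0
        for rv in r2:
            shifted = np.zeros_like(pmf)
            shifted[rv:] = pmf[: total + 1 - rv]
            pmf = 0.5 * (pmf + shifted)
        idx = int(np.rint(2 * w_plus))
        p = _two_sided_from_pmf(pmf, idx)
        method = "signed-rank exact"
    else:
        mu = n * (n + 1) / 4.0
        _, counts = np.unique(r, return_counts=True)
        tie = (counts**3 - counts).sum() / 48.0
        var = n * (n + 1) * (2 * n + 1) / 24.0 - tie
        z = (w_plus - mu) / np.sqrt(var)
        p = float(2 * sstats.norm.sf(abs(z)))
        method = "signed-rank normal approximation"
    return TestResult(statistic=w_plus, p=min(p, 1.0), n=n, method=method)


def _rank_sum_pmf(N: int, n1: int) -> np.ndarray:
    """Exact pmf of the rank sum of n1 untied ranks drawn from 1..N."""
    max_s = n1 * (2 * N - n1 + 1) // 2
    ways = np.zeros((n1 + 1, max_s + 1))
    ways[0, 0] = 1.0
    for rank in range(1, N + 1):
        for k in range(min(rank, n1), 0, -1):
            ways[k, rank:] += ways[k - 1, : max_s + 1 - rank]
    pmf = ways[n1]
    return pmf / pmf.sum()


def wilcoxon_rank_sum(a, b, exact_max_min_n: int = 10) -> TestResult:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test.

    Exact when the smaller group has <= `exact_max_min_n` observations and
    the pooled sample has no ties; otherwise normal approximation with tie
    correction.  The reported statistic is the rank sum of the first group.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    a = a[np.isfinite(a)]
    b = b[np.isfinite(b)]
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    n1, n2 = a.size, b.size
    N = n1 + n2
    pooled = np.concatenate([a, b])
    ranks = _midranks(pooled)
    w = float(ranks[:n1].sum())
    has_ties = np.unique(pooled).size < N
    if min(n1, n2) <= exact_max_min_n and not has_ties:
        pmf = _rank_sum_pmf(N, n1)
        min_s = n1 * (n1 + 1) // 2
        idx = int(np.rint(w)) - min_s
        p = _two_sided_from_pmf(pmf[min_s:], idx) if idx >= 0 else 1.0
        method = "rank-sum exact"
    else:
        mu = n1 * (N + 1) / 2.0
        _, counts = np.unique(pooled, return_counts=True)
        tie = (counts**3 - counts).sum() / (N * (N - 1))
        var = n1 * n2 / 12.0 * ((N + 1) - tie)
        if var <= 0:
            return TestResult(statistic=w, p=1.0, n=N,
                              method="rank-sum degenerate (all tied)")
        z = (w - mu) / np.sqrt(var)
        p = float(2 * sstats.norm.sf(abs(z)))
        method = "rank-sum normal approximation"
    return TestResult(statistic=w, p=min(p, 1.0), n=N, method=method)


def pairwise_location_ttests(table, value_col: str = "value",
                             subject_col: str = "subject",
                             location_col: str = "location",
                             alpha: float = 0.05,
                             min_pairs: int = 3) -> list[LocationComparison]:
    """Paired t-tests between all location pairs with Bonferroni correction.

    `table` holds one row per (subject, location) with the per-subject mean
    of the channel under test.  Each unordered location pair is tested on the
    subjects measured at both; the significance threshold is alpha divided by
    the number of pairs (0.005 for five locations).  Pairs with fewer than
    `min_pairs` complete subjects are reported unskipped with a note.
    """
    import pandas as pd

    df = pd.DataFrame(table)
    locations = sorted(df[location_col].unique())
    pairs = list(combinations(locations, 2))
    threshold = alpha / len(pairs)
    wide = df.pivot_table(index=subject_col, columns=location_col,
                          values=value_col, aggfunc="mean")
    out = []
    for la, lb in pairs:
        sub = wide[[la, lb]].dropna()
        if len(sub) < min_pairs:
            out.append(LocationComparison(pair=(la, lb), mean_diff=np.nan,
                                          statistic=np.nan, p=np.nan, n=len(sub),
                                          significant=False, threshold=threshold,
                                          note=f"skipped: only {len(sub)} complete pairs"))
            continue
        diff = sub[la] - sub[lb]
        if np.allclose(diff, diff.iloc[0]) and diff.iloc[0] == 0:
            t_stat, p = 0.0, 1.0
        else:
            t_stat, p = sstats.ttest_rel(sub[la], sub[lb])
        out.append(LocationComparison(pair=(la, lb), mean_diff=float(diff.mean()),
                                      statistic=float(t_stat), p=float(p), n=len(sub),
                                      significant=bool(p < threshold),
                                      threshold=threshold))
    return out
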