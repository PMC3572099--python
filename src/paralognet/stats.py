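"""Shared exact and rank statistics.

All comparative results in the pipeline funnel through four procedures:
Fisher's exact test on 2x2 contingency tables, the Wilcoxon rank-sum test,
the Kruskal-Wallis test, and Benjamini-Hochberg FDR adjustment.  They are
collected here so every stage quotes the same conventions:

* Fisher two-sided p-values sum point probabilities over all tables with the
  observed margins whose probability does not exceed the observed table's
  (R's convention, with a 1+1e-7 tolerance factor on the comparison).
* Wilcoxon uses mid-ranks for ties; exact enumeration when the pooled sample
  is small, a tie- and continuity-corrected normal approximation otherwise.
* Kruskal-Wallis uses the tie-corrected H statistic with a chi-square
  reference distribution on (groups - 1) degrees of freedom.

Coordinates and counts are plain Python ints/floats; no stage should need to
call scipy directly for these tests.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb, sqrt

import numpy as np
from scipy import stats as _sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ContingencyTable",
    "fisher_exact",
    "wilcoxon_rank_sum",
    "kruskal_wallis",
    "benjamini_hochberg",
    "odds_ratio",
]

#: pooled-sample size at or below which the Wilcoxon p-value is computed by
#: exhaustive enumeration of rank assignments (tie-aware).
WILCOXON_EXACT_MAX_N = 12


@dataclass(frozen=True)
class ContingencyTable:
    """A 2x2 table of non-negative integer counts.

    Layout::

            success   failure
        A      a         b
        B      c         d
    """

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for cell in (self.a, self.b, self.c, self.d):
            if int(cell) != cell or cell < 0:
                raise ValueError(f"contingency cells must be non-negative integers, got {cell!r}")
        if self.a + self.b + self.c + self.d == 0:
            raise ValueError("contingency table has no observations")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=np.int64)


def fisher_exact(table: ContingencyTable | tuple | list) -> float:
    """Two-sided Fisher exact test p-value for a 2x2 table.

    Accepts a :class:`ContingencyTable` or a nested pair ``[[a, b], [c, d]]``.
    """
    t = _as_table(table)
    _, p = _sps.fisher_exact(t.as_array(), alternative="two-sided")
    # scipy returns p in [0, 1]; clip tiny negative rounding
    return float(min(max(p, 0.0), 1.0))


def odds_ratio(table: ContingencyTable | tuple | list) -> float:
    """Sample odds ratio a*d / (b*c); inf when b*c == 0 and a*d > 0, nan for 0/0."""
    t = _as_table(table)
    num, den = t.a * t.d, t.b * t.c
    if den == 0:
        return float("nan") if num == 0 else float("inf")
    return num / den


def _as_table(table) -> ContingencyTable:
    if isinstance(table, ContingencyTable):
        return table
    (a, b), (c, d) = table
    return ContingencyTable(int(a), int(b), int(c), int(d))


def _midranks(values: np.ndarray) -> np.ndarray:
    return _sps.rankdata(values, method="average")


def wilcoxon_rank_sum(sample_a, sample_b) -> tuple[float, float]:
    """Wilcoxon rank-sum (Mann-Whitney) test, two-sided.

    Returns ``(W, p)`` where W is the rank-sum statistic of ``sample_a``
    (mid-ranks for ties).  Exact p by enumeration of all C(n, n_a) rank
    assignments when the pooled size is at most ``WILCOXON_EXACT_MAX_N``,
    otherwise normal approximation with tie correction and a 0.5 continuity
    correction.  Degenerate input (every pooled value identical) returns p=1.
    """
    x = np.asarray(sample_a, dtype=float)
    y = np.asarray(sample_b, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    ranks = _midranks(pooled)
    w_obs = float(ranks[: x.size].sum())
    if np.all(pooled == pooled[0]):
        return w_obs, 1.0

    n, na = pooled.size, x.size
    if n <= WILCOXON_EXACT_MAX_N:
        # exact, tie-aware: enumerate every subset of size na of the pooled
        # mid-ranks; two-sided p doubles the smaller tail (capped at 1)
        mu = na * (n + 1) / 2.0
        dev_obs = abs(w_obs - mu)
        total = comb(n, na)
        extreme = sum(
            1 for idx in combinations(range(n), na) if abs(sum(ranks[list(idx)]) - mu) >= dev_obs - 1e-9
        )
        return w_obs, min(1.0, extreme / total)

    nb = y.size
    mu = na * (n + 1) / 2.0
    # tie correction on the variance
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(((counts**3 - counts)).sum())
    var = na * nb / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if var <= 0:
        return w_obs, 1.0
    z = (abs(w_obs - mu) - 0.5) / sqrt(var)
    p = 2.0 * _sps.norm.sf(max(z, 0.0))
    return w_obs, float(min(1.0, p))


def kruskal_wallis(groups) -> tuple[float, float]:
    """Tie-corrected Kruskal-Wallis H and chi-square p over >=2 groups."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValueError("kruskal_wallis needs at least two groups")
    for g in groups:
        if g.size == 0:
            raise ValueError("every group must be non-empty")
    pooled = np.concatenate(groups)
    if np.all(pooled == pooled[0]):
        return 0.0, 1.0
    h, p = _sps.kruskal(*groups)
    return float(h), float(p)


def benjamini_hochberg(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, order-preserving."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return q
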