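"""Over-representation statistics shared by GO and TF enrichment.

The test is the one-sided hypergeometric upper tail (equivalently a
one-sided Fisher exact test): given a universe of N genes of which K carry
some property, and a selection of n genes of which k carry it, the p-value
is P(X >= k) for X ~ Hypergeometric(N, K, n). Multiple testing is handled
with Benjamini-Hochberg step-up FDR control.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from scipy.stats import hypergeom

__all__ = ["EnrichmentCount", "AdjustedResult", "hypergeom_pvalue", "bh_adjust",
           "select_significant"]


@dataclass(frozen=True)
class EnrichmentCount:
    """The 2x2 contingency counts of an over-representation test.

    k: property-carrying genes in the selection; n: selection size;
    K: property-carrying genes in the universe; N: universe size.
    """

    k: int
    n: int
    K: int
    N: int

    def __post_init__(self):
        if not (0 <= self.k <= min(self.n, self.K)):
            raise ValueError(f"require 0 <= k <= min(n, K); got k={self.k}, n={self.n}, K={self.K}")
        if self.n > self.N or self.K > self.N:
            raise ValueError(f"require n <= N and K <= N; got n={self.n}, K={self.K}, N={self.N}")
        if self.k < self.n + self.K - self.N:
            raise ValueError(
                f"infeasible counts: k={self.k} < n+K-N={self.n + self.K - self.N}"
            )


@dataclass(frozen=True)
class AdjustedResult:
    id: str
    p: float
    q: float


def hypergeom_pvalue(c: EnrichmentCount) -> float:
    """One-sided upper-tail P(X >= k) under Hypergeometric(N, K, n).

    Delegates to scipy's survival function, which works with log-space
    binomial coefficients and is stable for extreme counts.
    """
    return float(hypergeom.sf(c.k - 1, c.N, c.K, c.n))


def bh_adjust(pvals: Sequence[tuple[str, float]]) -> list[AdjustedResult]:
    """Benjamini-Hochberg step-up adjustment.

    q_(i) = min_{j >= i} min(1, p_(j) * m / j) over p-values sorted
    ascending. Equal p-values receive equal q by construction. Results are
    returned in the input order.
    """
    for _id, p in pvals:
        if not (0.0 <= p <= 1.0):
            raise ValueError(f"p-value for {_id!r} outside [0, 1]: {p}")
    m = len(pvals)
    if m == 0:
        return []
    # sort by (p, id): the id tie-break fixes iteration order deterministically;
    # q values are unaffected by how ties are ordered
    order = sorted(range(m), key=lambda i: (pvals[i][1], pvals[i][0]))
    q_sorted = [0.0] * m
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, min(1.0, pvals[i][1] * m / rank))
        q_sorted[rank - 1] = running
    q_by_index = {order[r]: q_sorted[r] for r in range(m)}
    return [AdjustedResult(id=pvals[i][0], p=pvals[i][1], q=q_by_index[i]) for i in range(m)]


def select_significant(results: Iterable[AdjustedResult], alpha: float) -> list[AdjustedResult]:
    """Items with q <= alpha, input order preserved."""
    return [r for r in results if r.q <= alpha]
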