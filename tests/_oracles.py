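"""Naive independent reference implementations used only by tests.

Everything here is deliberately brute-force and shares no code path with
the package: exhaustive draw enumeration for the hypergeometric tail,
exact-fraction tail sums, quadratic all-pairs interval scans, O(m^2)
step-up adjustment and per-gene DFS ancestor closure.
"""

from __future__ import annotations

import math
from fractions import Fraction
from itertools import combinations


def enum_hypergeom_tail(N: int, K: int, n: int, k: int) -> Fraction:
    """P(X >= k) by enumerating all C(N, n) draws from a labelled universe."""
    universe = range(N)
    special = set(range(K))
    hits = sum(1 for draw in combinations(universe, n) if len(special & set(draw)) >= k)
    return Fraction(hits, math.comb(N, n))


def frac_hypergeom_tail(N: int, K: int, n: int, k: int) -> Fraction:
    """P(X >= k) as an exact fraction via binomial-coefficient tail sum."""
    total = math.comb(N, n)
    acc = 0
    for j in range(k, min(n, K) + 1):
        if n - j > N - K:
            continue
        acc += math.comb(K, j) * math.comb(N - K, n - j)
    return Fraction(acc, total)


def naive_bh(pvals: list[float]) -> list[float]:
    """Step-up BH by the textbook definition, O(m^2), input order preserved."""
    m = len(pvals)
    order = sorted(range(m), key=lambda i: pvals[i])
    q = [0.0] * m
    for rank_pos, i in enumerate(order, start=1):
        q[i] = min(
            min(1.0, pvals[order[j - 1]] * m / j)
            for j in range(rank_pos, m + 1)
        )
    return q


def brute_overlap_pairs(peak_sets, regions, min_overlap_bp: int = 1) -> set:
    """All (tf_id, gene_id) with >= min_overlap_bp intersection, by full scan.

    ``peak_sets`` is an iterable with .tf_id and .peaks; ``regions`` an
    iterable of objects with .gene_id/.chrom/.start/.end.
    """
    pairs = set()
    for ps in peak_sets:
        for p in ps.peaks:
            for r in regions:
                if p.chrom != r.chrom:
                    continue
                if min(p.end, r.end) - max(p.start, r.start) >= min_overlap_bp:
                    pairs.add((ps.tf_id, r.gene_id))
    return pairs


def dfs_closure(parents: dict[str, set[str]], term: str) -> set[str]:
    """All ancestors of ``term`` (excluding itself) by explicit DFS."""
    seen: set[str] = set()
    stack = list(parents.get(term, ()))
    while stack:
        t = stack.pop()
        if t in seen:
            continue
        seen.add(t)
        stack.extend(parents.get(t, ()))
    return seen
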