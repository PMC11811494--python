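"""TF binding-peak enrichment in the promoters of a DEG list.

For each TF with at least one target gene in the universe, the test asks
whether the TF's targets are over-represented among the differentially
expressed genes: N = universe size, K = TF targets in the universe,
n = DEG-list size, k = TF targets among the DEGs, one-sided hypergeometric
p, BH-adjusted across all TFs tested in that direction. Up- and
down-regulated DEG lists are tested independently (separate BH families);
a TF passing q <= alpha (default 0.001) is called enriched and becomes a
candidate regulator for network reconstruction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping

import pandas as pd

from .peak_targets import TargetMap
from .stats_core import EnrichmentCount, bh_adjust, hypergeom_pvalue

__all__ = ["TFEnrichmentRecord", "enrich_tfs", "run_both_directions"]

logger = logging.getLogger(__name__)

DEFAULT_TF_FDR = 0.001


@dataclass(frozen=True)
class TFEnrichmentRecord:
    tf_id: str
    tf_family: str
    direction_tested: str  # "up" | "down"
    counts: EnrichmentCount
    p: float
    q: float


def enrich_tfs(target_map: TargetMap,
               deg_set: Iterable[str],
               universe: Iterable[str],
               alpha: float = DEFAULT_TF_FDR,
               tf_families: Mapping[str, str] | None = None,
               direction: str = "up") -> list[TFEnrichmentRecord]:
    """Test each TF's targets for over-representation in ``deg_set``.

    ``universe`` is every gene with a defined regulatory region. TFs with
    zero targets inside the universe are skipped (and logged) rather than
    assigned p=1, so the BH family contains only informative tests.
    Records are returned sorted by (p, tf_id); filter on ``q <= alpha``
    for the enriched subset.
    """
    universe = set(universe)
    deg_list = list(dict.fromkeys(deg_set))
    stray = [g for g in deg_list if g not in universe]
    if stray:
        raise ValueError(f"DEG list contains genes outside the universe: {sorted(stray)}")
    deg = set(deg_list)
    N, n = len(universe), len(deg)
    families = tf_families or {}

    tested: list[tuple[str, EnrichmentCount]] = []
    for tf in sorted(target_map.tfs()):
        targets = target_map.targets_of(tf) & universe
        if not targets:
            logger.info("TF %s has no targets in the universe; skipped", tf)
            continue
        c = EnrichmentCount(k=len(targets & deg), n=n, K=len(targets), N=N)
        tested.append((tf, c))
    if not tested:
        return []

    adjusted = bh_adjust([(tf, hypergeom_pvalue(c)) for tf, c in tested])
    records = [
        TFEnrichmentRecord(
            tf_id=tf, tf_family=families.get(tf, "unknown"),
            direction_tested=direction, counts=c, p=adj.p, q=adj.q,
        )
        for (tf, c), adj in zip(tested, adjusted)
    ]
    records.sort(key=lambda r: (r.p, r.tf_id))
    return records


def run_both_directions(target_map: TargetMap,
                        udegs: Iterable[str],
                        ddegs: Iterable[str],
                        universe: Iterable[str],
                        alpha: float = DEFAULT_TF_FDR,
                        tf_families: Mapping[str, str] | None = None,
                        ) -> tuple[list[TFEnrichmentRecord], list[TFEnrichmentRecord]]:
    """Enrichment run independently on up- and down-regulated DEG lists.

    BH correction is applied within each direction separately. Returns the
    records with q <= alpha per direction. Overlapping DEG lists are an
    error (a gene cannot be both up- and down-regulated).
    """
    uset, dset = set(udegs), set(ddegs)
    overlap = uset & dset
    if overlap:
        raise ValueError(f"uDEG and dDEG lists overlap: {sorted(overlap)}")
    up = enrich_tfs(target_map, uset, universe, alpha, tf_families, direction="up") if uset else []
    down = enrich_tfs(target_map, dset, universe, alpha, tf_families, direction="down") if dset else []
    return ([r for r in up if r.q <= alpha], [r for r in down if r.q <= alpha])


def records_table(records: Iterable[TFEnrichmentRecord]) -> pd.DataFrame:
    rows = [{
        "tf_id": r.tf_id, "tf_family": r.tf_family, "direction": r.direction_tested,
        "k": r.counts.k, "n": r.counts.n, "K": r.counts.K, "N": r.counts.N,
        "p": r.p, "q": r.q,
    } for r in records]
    return pd.DataFrame(rows, columns=["tf_id", "tf_family", "direction",
                                       "k", "n", "K", "N", "p", "q"])
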