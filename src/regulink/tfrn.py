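"""TF-TF regulatory network reconstruction, regulation types and hubs.

The network's nodes are the TFs that passed binding-peak enrichment; a
directed edge runs from regulator A to target B when a binding peak of A
lies in the 5' regulatory region of the gene encoding B. Each TF is
classified by regulation type from two observables: the DEG direction its
binding sites are enriched in, and the TF gene's own differential
expression:

    ============  =================  ======
    TF's own DEG  enriched in        type
    ============  =================  ======
    up            uDEG promoters     UA  (upregulated activator)
    up            dDEG promoters     US  (upregulated suppressor)
    down          dDEG promoters     DA  (downregulated activator)
    down          uDEG promoters     DS  (downregulated suppressor)
    not a DEG     either             untyped
    ============  =================  ======

An upregulated activator is induced by the stimulus and drives its targets
up; a downregulated suppressor is repressed by the stimulus, passively
releasing its targets. Hubs are the most connected nodes by total degree.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Mapping

import networkx as nx
import pandas as pd

from .annotation_io import GeneModel
from .errors import UnknownGeneError
from .peak_targets import Peak, TargetMap

__all__ = ["RegulationType", "TFNode", "TFRNEdge", "TFRN",
           "classify_regulation", "build_tfrn", "hubs"]


class RegulationType(str, Enum):
    UA = "UA"
    US = "US"
    DA = "DA"
    DS = "DS"
    UNTYPED = "untyped"


_RULES = {
    ("up", "up"): RegulationType.UA,
    ("up", "down"): RegulationType.US,
    ("down", "down"): RegulationType.DA,
    ("down", "up"): RegulationType.DS,
}


def classify_regulation(tf_id: str, enriched_in: str, tf_deg_status: str) -> RegulationType:
    """Regulation type from (direction enriched in, TF's own DEG status).

    ``enriched_in`` is the DEG direction whose promoters the TF's peaks are
    enriched in ('up' or 'down'); ``tf_deg_status`` is 'up', 'down' or
    'none'. A TF that is not itself differentially expressed is 'untyped'.
    """
    if enriched_in not in ("up", "down"):
        raise ValueError(f"TF {tf_id}: enriched_in must be 'up' or 'down', got {enriched_in!r}")
    if tf_deg_status not in ("up", "down", "none"):
        raise ValueError(f"TF {tf_id}: tf_deg_status must be up/down/none, got {tf_deg_status!r}")
    return _RULES.get((tf_deg_status, enriched_in), RegulationType.UNTYPED)


@dataclass(frozen=True)
class TFNode:
    """A network member: an enrichment-passing TF and its classification inputs."""

    tf_id: str
    enriched_in: str  # 'up' | 'down'
    deg_status: str = "none"  # 'up' | 'down' | 'none'
    family: str = "unknown"

    @property
    def regulation_type(self) -> RegulationType:
        return classify_regulation(self.tf_id, self.enriched_in, self.deg_status)


@dataclass(frozen=True)
class TFRNEdge:
    regulator: str
    target: str
    peaks: tuple[Peak, ...]

    @property
    def is_self_loop(self) -> bool:
        return self.regulator == self.target


class TFRN:
    """The reconstructed directed TF-TF network."""

    def __init__(self, nodes: Iterable[TFNode], edges: Iterable[TFRNEdge]):
        self.nodes: dict[str, list[TFNode]] = {}
        for n in nodes:
            # a TF enriched in both directions keeps one graph node, both labels
            self.nodes.setdefault(n.tf_id, []).append(n)
        self.edges: list[TFRNEdge] = sorted(edges, key=lambda e: (e.regulator, e.target))
        for e in self.edges:
            if e.regulator not in self.nodes or e.target not in self.nodes:
                raise ValueError(f"edge {e.regulator}->{e.target} references a non-member TF")

    def types_of(self, tf_id: str) -> tuple[RegulationType, ...]:
        return tuple(n.regulation_type for n in self.nodes[tf_id])

    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph()
        for tf_id, labels in self.nodes.items():
            g.add_node(
                tf_id,
                regulation_type=",".join(n.regulation_type.value for n in labels),
                family=labels[0].family,
            )
        for e in self.edges:
            g.add_edge(e.regulator, e.target,
                       n_peaks=len(e.peaks), self_loop=e.is_self_loop)
        return g

    def degree(self, tf_id: str) -> int:
        """Total degree (in + out); a self-loop contributes once."""
        d = 0
        for e in self.edges:
            if e.is_self_loop:
                d += int(e.regulator == tf_id)
            else:
                d += int(e.regulator == tf_id) + int(e.target == tf_id)
        return d

    def edge_table(self) -> pd.DataFrame:
        rows = [
            (e.regulator, e.target, p.chrom, p.start, p.end, e.is_self_loop)
            for e in self.edges for p in e.peaks
        ]
        return pd.DataFrame(rows, columns=["regulator", "target", "peak_chrom",
                                           "peak_start", "peak_end", "self_loop"])

    def node_table(self) -> pd.DataFrame:
        rows = [
            (tf, ",".join(t.value for t in self.types_of(tf)),
             labels[0].family, self.degree(tf),
             sum(1 for e in self.edges if e.regulator == tf),
             sum(1 for e in self.edges if e.target == tf))
            for tf, labels in sorted(self.nodes.items())
        ]
        return pd.DataFrame(rows, columns=["tf_id", "regulation_type", "family",
                                           "degree", "out_degree", "in_degree"])

    def write(self, out_dir, prefix: str = "tfrn") -> None:
        """Export edge list TSV, node table TSV and GraphML."""
        from pathlib import Path
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        self.edge_table().to_csv(out_dir / f"{prefix}_edges.tsv", sep="\t", index=False)
        self.node_table().to_csv(out_dir / f"{prefix}_nodes.tsv", sep="\t", index=False)
        nx.write_graphml(self.to_networkx(), out_dir / f"{prefix}.graphml")


def build_tfrn(tf_nodes: Iterable[TFNode],
               gene_models: Mapping[str, GeneModel],
               target_map: TargetMap,
               include_untyped: bool = True) -> TFRN:
    """Reconstruct the TF-TF network from the promoter target map.

    Edge A->B exists iff (A, gene(B)) is in ``target_map`` — i.e. A's peak
    was mapped into B's 5' regulatory region under whatever peak-set filter
    and upstream length produced the map. Every TF must resolve to a
    GeneModel (to locate its promoter). Self-loops (a TF binding its own
    promoter) are retained and flagged. ``include_untyped=False`` drops
    TFs that are not themselves DEGs.
    """
    nodes = list(tf_nodes)
    if not include_untyped:
        nodes = [n for n in nodes if n.regulation_type is not RegulationType.UNTYPED]
    missing = sorted({n.tf_id for n in nodes} - set(gene_models))
    if missing:
        raise UnknownGeneError(f"TF(s) without a gene model: {missing}")
    member_ids = {n.tf_id for n in nodes}
    edges = []
    for regulator in sorted(member_ids):
        for target in sorted(member_ids):
            key = (regulator, target)
            if key in target_map:
                edges.append(TFRNEdge(regulator=regulator, target=target,
                                      peaks=tuple(target_map.entries[key])))
    return TFRN(nodes, edges)


def hubs(network: TFRN, top: int = 5) -> list[tuple[str, int]]:
    """The ``top`` most connected TFs by total degree.

    Ties share a rank: every TF tied with the cut-off degree is included,
    so the result may exceed ``top``. Ordering is (degree desc, tf_id asc)
    for determinism.
    """
    if top < 1:
        raise ValueError(f"top must be >= 1, got {top}")
    ranked = sorted(((tf, network.degree(tf)) for tf in network.nodes),
                    key=lambda x: (-x[1], x[0]))
    if len(ranked) <= top:
        return ranked
    cutoff = ranked[top - 1][1]
    return [r for r in ranked if r[1] >= cutoff]
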