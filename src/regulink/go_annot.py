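"""Gene Ontology parsing, annotation propagation and over-representation.

The ontology is a DAG of terms linked by ``is_a`` and ``part_of``
relations. Gene annotations (GAF 2.x) attach terms to genes with evidence
codes; the true-path rule means a gene annotated to a term is implicitly
annotated to every ancestor, so annotations are propagated up the DAG
before testing. Functional annotation of a gene list is then a per-term
hypergeometric over-representation test against the annotated universe,
BH-corrected across all tested terms. Evidence codes are carried through
to the output and never filtered (electronic IEA annotations are kept).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import networkx as nx
import obonet
import pandas as pd

from .errors import CycleError, NoAnnotatedGenesError, ParseError
from .stats_core import EnrichmentCount, bh_adjust, hypergeom_pvalue

__all__ = ["GOTerm", "Ontology", "GeneAnnotation", "EnrichedTerm",
           "parse_obo", "parse_gaf", "propagate", "func_annot"]

NAMESPACES = ("biological_process", "molecular_function", "cellular_component")

_PARENT_RELATIONS = ("is_a", "part_of")

# GAF 2.x column indices (0-based)
_GAF_COLS = 17
_GAF_MIN_COLS = 15
_COL_GENE = 1
_COL_QUALIFIER = 3
_COL_TERM = 4
_COL_EVIDENCE = 6
_COL_ASPECT = 8


@dataclass(frozen=True)
class GOTerm:
    term_id: str
    name: str
    namespace: str
    parents: frozenset[str]
    obsolete: bool = False


class Ontology:
    """A GO DAG restricted to is_a/part_of parentage.

    Obsolete terms are retained for lookup but excluded from the DAG (they
    have no parents and never receive propagated annotations).
    """

    def __init__(self, terms: Iterable[GOTerm]):
        self.terms: dict[str, GOTerm] = {t.term_id: t for t in terms}
        live = {tid for tid, t in self.terms.items() if not t.obsolete}
        for t in self.terms.values():
            if t.obsolete:
                continue
            unknown = t.parents - live
            if unknown:
                raise ParseError(
                    f"term {t.term_id} references unknown parent(s): {sorted(unknown)}"
                )
        g = nx.DiGraph()
        g.add_nodes_from(live)
        for t in self.terms.values():
            if not t.obsolete:
                g.add_edges_from((t.term_id, p) for p in t.parents)
        if not nx.is_directed_acyclic_graph(g):
            cycle = nx.find_cycle(g)
            raise CycleError(f"ontology contains a cycle: {' -> '.join(e[0] for e in cycle)}")
        self._graph = g  # edges child -> parent
        self._ancestors: dict[str, frozenset[str]] = {}

    def __contains__(self, term_id: str) -> bool:
        return term_id in self.terms

    def __getitem__(self, term_id: str) -> GOTerm:
        return self.terms[term_id]

    def __len__(self) -> int:
        return len(self.terms)

    def ancestors(self, term_id: str) -> frozenset[str]:
        """All is_a/part_of ancestors of a term (excluding the term itself)."""
        if term_id not in self._ancestors:
            self._ancestors[term_id] = frozenset(nx.descendants(self._graph, term_id))
        return self._ancestors[term_id]

    def namespace_terms(self, namespace: str) -> set[str]:
        return {tid for tid, t in self.terms.items()
                if t.namespace == namespace and not t.obsolete}


class GeneAnnotation:
    """gene_id -> {term_id -> set of evidence codes}."""

    def __init__(self, data: Mapping[str, Mapping[str, set[str]]] | None = None):
        self.data: dict[str, dict[str, set[str]]] = {
            g: {t: set(ev) for t, ev in terms.items()} for g, terms in (data or {}).items()
        }

    def add(self, gene_id: str, term_id: str, evidence: str) -> None:
        self.data.setdefault(gene_id, {}).setdefault(term_id, set()).add(evidence)

    def genes(self) -> set[str]:
        return set(self.data)

    def terms_of(self, gene_id: str) -> dict[str, set[str]]:
        return self.data.get(gene_id, {})

    def __len__(self) -> int:
        return len(self.data)


@dataclass(frozen=True)
class EnrichedTerm:
    """One over-represented GO term with its supporting gene sublist."""

    term_id: str
    name: str
    p: float
    q: float
    genes: tuple[tuple[str, frozenset[str]], ...]  # (gene_id, evidence codes)
    counts: EnrichmentCount = field(compare=False, default=None)

    @property
    def gene_ids(self) -> tuple[str, ...]:
        return tuple(g for g, _ev in self.genes)


def parse_obo(path) -> Ontology:
    """Parse an OBO 1.2/1.4 ontology file.

    is_a and part_of relations become parent links; obsolete terms are
    flagged and excluded from the DAG. Cycles and unknown parents raise.
    """
    graph = obonet.read_obo(path, ignore_obsolete=False)
    terms = []
    for tid, data in graph.nodes(data=True):
        obsolete = str(data.get("is_obsolete", "false")).lower() == "true"
        parents: set[str] = set()
        if not obsolete:
            parents.update(data.get("is_a", []))
            for rel in data.get("relationship", []):
                rel_type, _, target = rel.partition(" ")
                if rel_type == "part_of":
                    parents.add(target.strip())
        terms.append(GOTerm(
            term_id=tid,
            name=data.get("name", tid),
            namespace=data.get("namespace", "biological_process"),
            parents=frozenset(parents),
            obsolete=obsolete,
        ))
    return Ontology(terms)


def parse_gaf(path) -> GeneAnnotation:
    """Parse GAF 2.x direct (unpropagated) annotations.

    Column 2 is the gene id, column 5 the term, column 7 the evidence code.
    Rows whose qualifier contains NOT are skipped; duplicate (gene, term)
    rows collapse with evidence-code union.
    """
    ann = GeneAnnotation()
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("!"):
                continue
            fields = line.split("\t")
            if len(fields) < _GAF_MIN_COLS:
                raise ParseError(
                    f"expected >= {_GAF_MIN_COLS} tab-separated columns, got {len(fields)}",
                    path=path, line_number=lineno,
                )
            gene_id = fields[_COL_GENE]
            term_id = fields[_COL_TERM]
            evidence = fields[_COL_EVIDENCE]
            if not gene_id or not term_id or not evidence:
                raise ParseError("empty gene id, term or evidence code",
                                 path=path, line_number=lineno)
            qualifier = fields[_COL_QUALIFIER]
            if "NOT" in qualifier.split("|"):
                continue
            ann.add(gene_id, term_id, evidence)
    return ann


def propagate(annotation: GeneAnnotation, ontology: Ontology) -> GeneAnnotation:
    """Close annotations under is_a/part_of ancestors (true-path rule).

    Evidence codes are carried upward unchanged; a term annotated through
    several children unions their codes. Terms absent from the ontology are
    dropped (they cannot be placed in the DAG).
    """
    out = GeneAnnotation()
    for gene, terms in annotation.data.items():
        for term, evidence in terms.items():
            if term not in ontology or ontology[term].obsolete:
                continue
            for target in {term} | set(ontology.ancestors(term)):
                for ev in evidence:
                    out.add(gene, target, ev)
    return out


def func_annot(genes: Iterable[str],
               annotation: GeneAnnotation,
               ontology: Ontology,
               universe: Iterable[str] | None = None,
               namespace: str = "biological_process",
               alpha: float = 0.05,
               min_term_size: int = 2,
               max_term_size: int | None = None,
               propagate_annotations: bool = True) -> list[EnrichedTerm]:
    """Functional annotation: GO over-representation of a gene list.

    The universe defaults to every gene with at least one (propagated)
    annotation in the chosen namespace; an explicit universe is intersected
    with that set. Per term with >= ``min_term_size`` selection hits the
    contingency counts are N=|annotated universe|, K=|universe genes
    annotated to the term|, n=|annotated selection|, k=|selection genes
    annotated to the term|; p is one-sided hypergeometric, q is BH over all
    tested terms. Terms with q <= alpha are returned sorted by ascending p
    (ties by term id), each with its gene sublist and evidence codes.
    """
    if namespace not in NAMESPACES:
        raise ValueError(f"unknown namespace {namespace!r}")
    ann = propagate(annotation, ontology) if propagate_annotations else annotation
    ns_terms = ontology.namespace_terms(namespace)

    gene_terms: dict[str, set[str]] = {}
    for g, terms in ann.data.items():
        in_ns = {t for t in terms if t in ns_terms}
        if in_ns:
            gene_terms[g] = in_ns

    univ = set(gene_terms)
    if universe is not None:
        univ &= set(universe)
    selection = [g for g in dict.fromkeys(genes) if g in univ]
    if not selection:
        raise NoAnnotatedGenesError(
            f"no gene in the selection carries a {namespace} annotation within the universe"
        )

    term_universe: dict[str, set[str]] = {}
    for g in univ:
        for t in gene_terms[g]:
            term_universe.setdefault(t, set()).add(g)

    sel_set = set(selection)
    N, n = len(univ), len(selection)
    tested = []
    for term in sorted(term_universe):
        hits = term_universe[term] & sel_set
        if len(hits) < min_term_size:
            continue
        if max_term_size is not None and len(term_universe[term]) > max_term_size:
            continue
        c = EnrichmentCount(k=len(hits), n=n, K=len(term_universe[term]), N=N)
        tested.append((term, c, hits))
    if not tested:
        return []

    adjusted = bh_adjust([(term, hypergeom_pvalue(c)) for term, c, _ in tested])
    results = []
    for (term, c, hits), adj in zip(tested, adjusted):
        if adj.q > alpha:
            continue
        gene_list = tuple(
            (g, frozenset(ann.terms_of(g)[term])) for g in sorted(hits)
        )
        results.append(EnrichedTerm(
            term_id=term, name=ontology[term].name, p=adj.p, q=adj.q,
            genes=gene_list, counts=c,
        ))
    results.sort(key=lambda r: (r.p, r.term_id))
    return results


def enrichment_table(results: Iterable[EnrichedTerm]) -> pd.DataFrame:
    """Tabular view of func_annot output (one row per enriched term)."""
    rows = []
    for r in results:
        rows.append({
            "term_id": r.term_id,
            "name": r.name,
            "k": r.counts.k, "n": r.counts.n, "K": r.counts.K, "N": r.counts.N,
            "p": r.p, "q": r.q,
            "genes": ",".join(f"{g}({'|'.join(sorted(ev))})" for g, ev in r.genes),
        })
    return pd.DataFrame(rows, columns=["term_id", "name", "k", "n", "K", "N", "p", "q", "genes"])
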