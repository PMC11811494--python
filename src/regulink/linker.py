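"""Join GO enrichment with TF->target mapping; emit the five output blocks.

A RegulatoryLink is the core triple: TF -> gene -> enriched biological
process, supported by a binding peak in the gene's promoter and the gene's
membership in the enriched term. The same triple set is re-presented four
ways — gene-centric (block 1), process-centric (block 2), TF-centric
(block 3) and flat (block 4) — while block 5 is the raw GO-enrichment
table the triples were drawn from.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from .go_annot import EnrichedTerm, enrichment_table
from .peak_targets import TargetMap

__all__ = ["RegulatoryLink", "OutputBlocks", "link", "emit_blocks"]

logger = logging.getLogger(__name__)

BLOCK_FILES = {
    "block1": "block1_genes.tsv",
    "block2": "block2_terms.tsv",
    "block3": "block3_tfs.tsv",
    "block4": "block4_triples.tsv",
    "block5": "block5_go_enrichment.tsv",
}


@dataclass(frozen=True)
class RegulatoryLink:
    tf_id: str
    tf_family: str
    gene_id: str
    term_id: str
    term_name: str
    evidence_codes: frozenset[str]


@dataclass
class OutputBlocks:
    block1: pd.DataFrame
    block2: pd.DataFrame
    block3: pd.DataFrame
    block4: pd.DataFrame
    block5: pd.DataFrame


def link(enriched_terms: Iterable[EnrichedTerm],
         target_map: TargetMap,
         tf_table: Mapping[str, str]) -> set[RegulatoryLink]:
    """One link per (tf, gene, term) with the gene in the term's sublist
    and the TF targeting the gene's promoter.

    ``tf_table`` maps tf_id -> family; a TF present in the target map but
    absent from the table gets family 'unknown' (with a warning). Genes of
    an enriched term that no TF targets produce no link here but are still
    carried into blocks 1/2 by :func:`emit_blocks`.
    """
    warned: set[str] = set()
    links: set[RegulatoryLink] = set()
    for term in enriched_terms:
        for gene_id, evidence in term.genes:
            for tf_id in target_map.tfs():
                if (tf_id, gene_id) not in target_map:
                    continue
                if tf_id not in tf_table and tf_id not in warned:
                    logger.warning("TF %s missing from the TF table; family set to 'unknown'", tf_id)
                    warned.add(tf_id)
                links.add(RegulatoryLink(
                    tf_id=tf_id,
                    tf_family=tf_table.get(tf_id, "unknown"),
                    gene_id=gene_id,
                    term_id=term.term_id,
                    term_name=term.name,
                    evidence_codes=frozenset(evidence),
                ))
    return links


def _fmt_ev(codes: Iterable[str]) -> str:
    return "|".join(sorted(codes))


def emit_blocks(links: set[RegulatoryLink],
                enriched_terms: Iterable[EnrichedTerm],
                out_dir=None) -> OutputBlocks:
    """Build the five result tables; write them as TSV if out_dir is given.

    Blocks 1-4 re-group the identical triple set; genes belonging to an
    enriched term but targeted by zero candidate TFs appear in blocks 1
    and 2 with an empty TF list and TF count 0. All tables are
    deterministically sorted, so identical inputs give byte-identical
    files. List-valued cells are comma-separated and sorted; TF families
    in parentheses; evidence codes pipe-separated in parentheses.
    """
    enriched_terms = list(enriched_terms)
    by_gene: dict[str, dict] = {}
    by_term: dict[str, dict] = {}
    by_tf: dict[str, dict] = {}

    # seed from the enrichment so TF-less genes are retained
    for term in enriched_terms:
        t = by_term.setdefault(term.term_id, {
            "name": term.name, "q": term.q, "genes": {}, "tfs": {},
        })
        for gene_id, evidence in term.genes:
            t["genes"][gene_id] = frozenset(evidence)
            g = by_gene.setdefault(gene_id, {"terms": {}, "tfs": {}})
            g["terms"][term.term_id] = (term.name, frozenset(evidence))

    for ln in links:
        by_gene[ln.gene_id]["tfs"][ln.tf_id] = ln.tf_family
        by_term[ln.term_id]["tfs"][ln.tf_id] = ln.tf_family
        tf = by_tf.setdefault(ln.tf_id, {"family": ln.tf_family, "genes": set(), "terms": set()})
        tf["genes"].add(ln.gene_id)
        tf["terms"].add(ln.term_id)

    block1 = pd.DataFrame(
        [{
            "gene_id": gene,
            "n_tfs": len(rec["tfs"]),
            "tfs": ",".join(f"{tf}({fam})" for tf, fam in sorted(rec["tfs"].items())),
            "n_terms": len(rec["terms"]),
            "terms": ",".join(
                f"{tid}({_fmt_ev(ev)})" for tid, (_name, ev) in sorted(rec["terms"].items())
            ),
        } for gene, rec in sorted(by_gene.items())],
        columns=["gene_id", "n_tfs", "tfs", "n_terms", "terms"],
    )

    block2 = pd.DataFrame(
        [{
            "term_id": tid,
            "term_name": rec["name"],
            "n_genes": len(rec["genes"]),
            "genes": ",".join(
                f"{g}({_fmt_ev(ev)})" for g, ev in sorted(rec["genes"].items())
            ),
            "n_tfs": len(rec["tfs"]),
            "tfs": ",".join(f"{tf}({fam})" for tf, fam in sorted(rec["tfs"].items())),
        } for tid, rec in sorted(by_term.items())],
        columns=["term_id", "term_name", "n_genes", "genes", "n_tfs", "tfs"],
    )

    block3 = pd.DataFrame(
        [{
            "tf_id": tf,
            "tf_family": rec["family"],
            "n_target_genes": len(rec["genes"]),
            "target_genes": ",".join(sorted(rec["genes"])),
            "n_terms": len(rec["terms"]),
            "terms": ",".join(sorted(rec["terms"])),
        } for tf, rec in sorted(by_tf.items())],
        columns=["tf_id", "tf_family", "n_target_genes", "target_genes", "n_terms", "terms"],
    )

    block4 = pd.DataFrame(
        sorted(
            (ln.gene_id, ln.tf_id, ln.tf_family, ln.term_id, ln.term_name,
             _fmt_ev(ln.evidence_codes))
            for ln in links
        ),
        columns=["gene_id", "tf_id", "tf_family", "term_id", "term_name", "evidence_codes"],
    )

    block5 = enrichment_table(enriched_terms)

    blocks = OutputBlocks(block1, block2, block3, block4, block5)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for name, fname in BLOCK_FILES.items():
            getattr(blocks, name).to_csv(out_dir / fname, sep="\t", index=False)
    return blocks
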