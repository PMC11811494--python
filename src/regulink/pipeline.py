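"""End-to-end orchestration: from annotation, peaks and gene lists to the
five output blocks and the TF-TF network.

Stages (each logged to stderr with counts and elapsed time):

1. parse the genome annotation and derive 5' regulatory regions;
2. load the peak collection and apply the sample-metadata filter;
3. map peaks onto regions to obtain the TF -> target assignment;
4. either take the supplied TF list, or identify TFs whose binding is
   over-represented in uDEG/dDEG promoters (separate BH families,
   q <= tf_fdr);
5. functionally annotate the DEG list (GO biological processes,
   q <= go_fdr);
6. join enrichment with targets into regulatory links, emit blocks 1-5,
   and (when enrichment directions are known) reconstruct the typed TF-TF
   network with hub ranking.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

from . import annotation_io, go_annot, linker, peak_targets, tf_enrichment, tfrn

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline", "read_gene_list"]


@dataclass
class PipelineConfig:
    """Tunable knobs, mirroring the command-line flags."""

    upstream_length: int = annotation_io.DEFAULT_UPSTREAM_LENGTH
    go_fdr: float = 0.05
    tf_fdr: float = tf_enrichment.DEFAULT_TF_FDR
    peak_filter: dict[str, str] = field(default_factory=dict)
    min_overlap_bp: int = 1
    namespace: str = "biological_process"
    min_term_size: int = 2
    include_untyped: bool = True


@dataclass
class PipelineResult:
    gene_models: dict
    regions: dict
    target_map: peak_targets.TargetMap
    tf_table: dict[str, str]
    up_tf_records: list
    down_tf_records: list
    enriched_terms: list
    links: set
    blocks: linker.OutputBlocks | None
    network: tfrn.TFRN | None
    hub_ranking: list


def read_gene_list(path) -> list[str]:
    """One gene ID per line; blank lines and '#' comments ignored."""
    out = []
    with open(path) as fh:
        for raw in fh:
            line = raw.strip()
            if line and not line.startswith("#"):
                out.append(line)
    return list(dict.fromkeys(out))


def _stage(name: str, t0: float, **counts) -> None:
    extras = " ".join(f"{k}={v}" for k, v in counts.items())
    logger.info("stage=%s elapsed=%.2fs %s", name, time.perf_counter() - t0, extras)


def run_pipeline(gff_path,
                 peaks_meta,
                 peaks_dir,
                 obo_path,
                 gaf_path,
                 degs: Iterable[str] | None = None,
                 udegs: Iterable[str] | None = None,
                 ddegs: Iterable[str] | None = None,
                 tf_list: Iterable[str] | None = None,
                 config: PipelineConfig | None = None,
                 out_dir=None) -> PipelineResult:
    """Run the full workflow.

    Either pass an explicit ``tf_list`` of candidate regulators, or leave
    it None to derive the TF list from binding-peak enrichment (requires
    ``udegs``/``ddegs``). ``degs`` defaults to the union of the directional
    lists. DEG identifiers absent from the annotation are dropped with a
    warning. When ``out_dir`` is given, all tables (blocks, TF enrichment,
    target map, network) are written beneath it.
    """
    cfg = config or PipelineConfig()
    u = list(udegs) if udegs is not None else []
    d = list(ddegs) if ddegs is not None else []
    deg_list = list(degs) if degs is not None else list(dict.fromkeys(u + d))
    if not deg_list:
        raise ValueError("no DEGs supplied")
    if tf_list is None and not (u or d):
        raise ValueError("either a TF list or directional DEG lists are required")

    t0 = time.perf_counter()
    genes = annotation_io.parse_gff3(gff_path)
    regions = annotation_io.regions_for_genes(genes, cfg.upstream_length)
    _stage("annotation", t0, genes=len(genes), upstream_length=cfg.upstream_length)

    t0 = time.perf_counter()
    collection = peak_targets.load_collection(peaks_meta, peaks_dir)
    filtered = peak_targets.filter_collection(collection, cfg.peak_filter)
    tf_families = {ps.tf_id: ps.tf_family for ps in filtered}
    _stage("peaks", t0, sets=len(collection), kept=len(filtered))

    t0 = time.perf_counter()
    target_map = peak_targets.map_targets(filtered, regions, cfg.min_overlap_bp)
    _stage("target_map", t0, pairs=len(target_map), tfs=len(target_map.tfs()))

    universe = set(regions)

    def _known(lst, label):
        known = [g for g in lst if g in universe]
        if len(known) < len(lst):
            logger.warning("%d %s gene(s) absent from the annotation; dropped",
                           len(lst) - len(known), label)
        return known

    u, d = _known(u, "uDEG"), _known(d, "dDEG")
    deg_list = _known(deg_list, "DEG")

    up_records: list = []
    down_records: list = []
    deg_status = {g: "up" for g in u} | {g: "down" for g in d}
    if tf_list is not None:
        tf_ids = list(dict.fromkeys(tf_list))
        nodes = None
    else:
        t0 = time.perf_counter()
        up_records, down_records = tf_enrichment.run_both_directions(
            target_map, u, d, universe, cfg.tf_fdr, tf_families)
        nodes = [
            tfrn.TFNode(r.tf_id, r.direction_tested,
                        deg_status.get(r.tf_id, "none"), r.tf_family)
            for r in up_records + down_records
        ]
        tf_ids = list(dict.fromkeys(n.tf_id for n in nodes))
        _stage("tf_enrichment", t0, up=len(up_records), down=len(down_records))

    t0 = time.perf_counter()
    ontology = go_annot.parse_obo(obo_path)
    annotation = go_annot.parse_gaf(gaf_path)
    enriched = go_annot.func_annot(
        deg_list, annotation, ontology,
        namespace=cfg.namespace, alpha=cfg.go_fdr, min_term_size=cfg.min_term_size)
    _stage("go_enrichment", t0, terms=len(enriched))

    t0 = time.perf_counter()
    tf_map = target_map.restrict_tfs(tf_ids)
    tf_table = {tf: tf_families.get(tf, "unknown") for tf in tf_ids}
    links = linker.link(enriched, tf_map, tf_table)
    blocks = linker.emit_blocks(
        links, enriched, None if out_dir is None else Path(out_dir))
    _stage("linking", t0, links=len(links))

    network = None
    hub_ranking: list = []
    if nodes:
        t0 = time.perf_counter()
        network = tfrn.build_tfrn(nodes, genes, target_map,
                                  include_untyped=cfg.include_untyped)
        hub_ranking = tfrn.hubs(network, top=5)
        _stage("tfrn", t0, nodes=len(network.nodes), edges=len(network.edges))

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        target_map.write_tsv(out_dir / "target_map.tsv")
        tf_enrichment.records_table(up_records + down_records).to_csv(
            out_dir / "tf_enrichment.tsv", sep="\t", index=False)
        if network is not None:
            network.write(out_dir)

    return PipelineResult(
        gene_models=genes, regions=regions, target_map=target_map,
        tf_table=tf_table, up_tf_records=up_records, down_tf_records=down_records,
        enriched_terms=enriched, links=links, blocks=blocks,
        network=network, hub_ranking=hub_ranking,
    )
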