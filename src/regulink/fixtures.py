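"""Seeded generator of toy regulatory-genomics datasets with planted signal.

The generator emulates, at desk scale, the inputs of a stimulus-response
study: a genome annotation, a DAP-seq-like peak collection with sample
metadata, a small GO DAG with gene annotations, and up/down DEG lists.
Signal is planted as TF -> gene-module -> process structure: each module
is a block of co-regulated genes annotated to one leaf GO term and placed
wholesale into one DEG direction; each planted regulator's peaks cover a
configurable fraction of its module genes' promoters, on top of uniform
background binding. Because the generator knows every peak it placed and
every gene it drew, it also emits truth tables — the exact target pairs,
enriched TFs/terms, regulatory links and regulation types the analysis
should recover — computed from its own bookkeeping rather than by running
the pipeline.

Genes are laid out on fixed-width slots wide enough that no two promoter
windows can overlap regardless of strand, and no window is clipped.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .stats_core import EnrichmentCount, bh_adjust, hypergeom_pvalue
from .tfrn import classify_regulation

__all__ = ["PlantedRegulator", "FixtureSpec", "FixtureBundle", "generate"]

_GENE_LEN = 500
_PEAK_LEN = 200
_EVIDENCE_CODES = ("IDA", "IEP", "HDA", "IEA")
_FAMILIES = ("AP2/ERF", "WRKY", "bZIP", "MYB", "NAC")

ROOT_TERM = "GO:0000001"
MID_STIMULUS = "GO:0000002"
MID_BACKGROUND = "GO:0000003"
BACKGROUND_TERM = "GO:0000100"
MF_TERM = "GO:0000200"


@dataclass(frozen=True)
class PlantedRegulator:
    """A TF planted to bind one module's promoters.

    ``term_index`` selects the module; ``direction`` must match that
    module's DEG direction; ``coverage`` is the fraction of module
    promoters carrying a peak; ``tf_status`` is the TF gene's own DEG
    direction, which (with ``direction``) determines the expected
    regulation type.
    """

    term_index: int
    direction: str  # 'up' | 'down'
    coverage: float
    tf_status: str  # 'up' | 'down' | 'none'


def _default_planting() -> dict[int, PlantedRegulator]:
    # one upregulated activator and one downregulated suppressor on the
    # up-module: the configuration observed in stimulus-response networks
    # where activation starts the response
    return {
        0: PlantedRegulator(term_index=0, direction="up", coverage=0.8, tf_status="up"),
        1: PlantedRegulator(term_index=0, direction="up", coverage=0.8, tf_status="down"),
    }


@dataclass
class FixtureSpec:
    """Study conditions for one synthetic bundle."""

    seed: int = 0
    n_chroms: int = 2
    n_genes: int = 400
    n_tfs: int = 10
    upstream_length: int = 1000
    n_terms: int = 2
    module_size: int = 40
    module_directions: tuple[str, ...] = ("up", "down")
    planted_regulators: dict[int, PlantedRegulator] = field(default_factory=_default_planting)
    tf_tf_edges: tuple[tuple[int, int], ...] = ((0, 1),)
    background_binding_prob: float = 0.1
    deg_fraction: float = 0.12
    include_decoy_sets: bool = True
    go_fdr: float = 0.05
    tf_fdr: float = 0.001
    min_term_size: int = 2

    def validate(self) -> None:
        if len(self.module_directions) != self.n_terms:
            raise ValueError("module_directions must have one entry per term")
        if self.n_terms * self.module_size + self.n_tfs > self.n_genes:
            raise ValueError("modules plus TF genes do not fit into n_genes")
        if not (0.0 <= self.background_binding_prob < 1.0):
            raise ValueError("background_binding_prob must be in [0, 1)")
        for tf_i, pr in self.planted_regulators.items():
            if not (0.0 < pr.coverage <= 1.0):
                raise ValueError(f"planted TF {tf_i}: coverage must be in (0, 1]")
            if pr.term_index >= self.n_terms:
                raise ValueError(f"planted TF {tf_i}: term index out of range")
            if pr.direction != self.module_directions[pr.term_index]:
                raise ValueError(
                    f"planted TF {tf_i}: direction {pr.direction!r} does not match "
                    f"module direction {self.module_directions[pr.term_index]!r}"
                )
            if tf_i >= self.n_tfs:
                raise ValueError(f"planted TF index {tf_i} out of range")


@dataclass
class FixtureBundle:
    """Paths and in-memory truth for one generated dataset."""

    out_dir: Path
    gff_path: Path
    peaks_meta: Path
    peaks_dir: Path
    obo_path: Path
    gaf_path: Path
    udegs_path: Path
    ddegs_path: Path
    degs_path: Path
    tf_ids: list[str]
    tf_families: dict[str, str]
    module_terms: list[str]
    module_genes: dict[str, list[str]]
    udegs: list[str]
    ddegs: list[str]
    planted: dict  # tf_id -> PlantedRegulator
    truth_pairs: set  # (tf, gene) promoter-binding pairs, filtered collection
    truth_tfs: dict  # direction -> set of expected-enriched tf ids
    truth_terms: set  # expected-enriched term ids (union DEG selection)
    truth_links: set  # (tf, gene, term)
    truth_types: dict  # tf -> expected regulation type string
    truth_edges: set  # (regulator, target) among expected-enriched TFs


def _place_genes(spec: FixtureSpec, rng) -> list[dict]:
    """Non-overlapping slot layout; promoters can never collide or clip."""
    slot = 2 * spec.upstream_length + _GENE_LEN + 100
    genes = []
    per_chrom = -(-spec.n_genes // spec.n_chroms)
    for i in range(spec.n_genes):
        chrom_i = i // per_chrom
        idx = i % per_chrom
        start0 = idx * slot + spec.upstream_length  # 0-based gene start
        strand = "+" if rng.random() < 0.5 else "-"
        genes.append({
            "gene_id": f"AT{chrom_i + 1}G{(idx + 1) * 10:05d}",
            "chrom": f"chr{chrom_i + 1}",
            "strand": strand,
            "start1": start0 + 1,
            "end1": start0 + _GENE_LEN,
        })
    return genes


def _promoter(g: dict, upstream: int) -> tuple[int, int]:
    """0-based half-open promoter window (layout guarantees no clipping)."""
    if g["strand"] == "+":
        end = g["start1"] - 1
        return end - upstream, end
    start = g["end1"]
    return start, start + upstream


def _peak_in(lo: int, hi: int, rng) -> tuple[int, int]:
    """A _PEAK_LEN peak uniformly placed inside [lo, hi)."""
    width = min(_PEAK_LEN, hi - lo)
    offset = int(rng.integers(0, hi - lo - width + 1))
    return lo + offset, lo + offset + width


def generate(spec: FixtureSpec, out_dir) -> FixtureBundle:
    """Write the bundle under ``out_dir`` and return paths plus truth."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    out_dir = Path(out_dir)
    peaks_dir = out_dir / "peaks"
    peaks_dir.mkdir(parents=True, exist_ok=True)

    genes = _place_genes(spec, rng)
    gene_ids = [g["gene_id"] for g in genes]
    by_id = {g["gene_id"]: g for g in genes}

    # --- roles: TF genes first, then modules, rest background -------------
    order = list(rng.permutation(spec.n_genes))
    tf_gene_idx = order[: spec.n_tfs]
    cursor = spec.n_tfs
    module_terms = [f"GO:{101 + t:07d}" for t in range(spec.n_terms)]
    module_genes: dict[str, list[str]] = {}
    for t, term in enumerate(module_terms):
        idx = order[cursor: cursor + spec.module_size]
        cursor += spec.module_size
        module_genes[term] = sorted(gene_ids[i] for i in idx)
    tf_ids = sorted(gene_ids[i] for i in tf_gene_idx)
    tf_families = {tf: _FAMILIES[i % len(_FAMILIES)] for i, tf in enumerate(tf_ids)}
    free_genes = sorted(
        set(gene_ids) - set(tf_ids) - {g for gs in module_genes.values() for g in gs}
    )

    # --- DEG lists --------------------------------------------------------
    per_direction = round(spec.deg_fraction * spec.n_genes)
    udegs: list[str] = []
    ddegs: list[str] = []
    for term, direction in zip(module_terms, spec.module_directions):
        (udegs if direction == "up" else ddegs).extend(module_genes[term])
    planted = {tf_ids[i]: pr for i, pr in spec.planted_regulators.items()}
    for tf, pr in sorted(planted.items()):
        if pr.tf_status == "up":
            udegs.append(tf)
        elif pr.tf_status == "down":
            ddegs.append(tf)
    pool = list(free_genes)
    rng.shuffle(pool)
    for lst in (udegs, ddegs):
        extra = max(0, per_direction - len(lst))
        lst.extend(pool[:extra])
        del pool[:extra]
    udegs, ddegs = sorted(set(udegs)), sorted(set(ddegs))

    # --- peaks ------------------------------------------------------------
    # one methylated-leaf set per TF (the analysis-grade condition), plus
    # optional decoy sets under other conditions that the filter must drop
    truth_pairs: set[tuple[str, str]] = set()
    set_rows = []
    for i, tf in enumerate(tf_ids):
        bound: set[str] = set()
        pr = planted.get(tf)
        if pr is not None:
            module = module_genes[module_terms[pr.term_index]]
            n_cov = max(1, round(pr.coverage * len(module)))
            chosen = sorted(rng.choice(module, size=n_cov, replace=False))
            bound.update(chosen)
        background = rng.random(spec.n_genes) < spec.background_binding_prob
        bound.update(g for g, hit in zip(gene_ids, background) if hit)
        for a, b in spec.tf_tf_edges:
            if tf == tf_ids[a]:
                bound.add(tf_ids[b])
        peaks = []
        for g in sorted(bound):
            lo, hi = _promoter(by_id[g], spec.upstream_length)
            s, e = _peak_in(lo, hi, rng)
            peaks.append((by_id[g]["chrom"], s, e))
            truth_pairs.add((tf, g))
        # a couple of gene-body peaks that must map to nothing
        for g in rng.choice(gene_ids, size=2, replace=False):
            gm = by_id[g]
            s, e = _peak_in(gm["start1"] - 1 + 50, gm["end1"] - 50, rng)
            peaks.append((gm["chrom"], s, e))
        set_id = f"SET{i:03d}_leafm"
        _write_bed(peaks_dir / f"{set_id}.bed", sorted(peaks))
        set_rows.append((set_id, tf, tf_families[tf], "leaf", "methylated", "dap-seq"))
        if spec.include_decoy_sets and i < 2:
            decoys = []
            for g in rng.choice(gene_ids, size=20, replace=False):
                lo, hi = _promoter(by_id[g], spec.upstream_length)
                s, e = _peak_in(lo, hi, rng)
                decoys.append((by_id[g]["chrom"], s, e))
            decoy_id = f"SET{i:03d}_leafu"
            _write_bed(peaks_dir / f"{decoy_id}.bed", sorted(decoys))
            set_rows.append((decoy_id, tf, tf_families[tf], "leaf", "unmethylated", "dap-seq"))

    peaks_meta = out_dir / "peaks_meta.tsv"
    with open(peaks_meta, "w") as fh:
        fh.write("set_id\ttf_id\ttf_family\ttissue\tdna_state\tassay\n")
        for row in set_rows:
            fh.write("\t".join(row) + "\n")

    # --- ontology ---------------------------------------------------------
    parents: dict[str, set[str]] = {
        ROOT_TERM: set(),
        MID_STIMULUS: {ROOT_TERM},
        MID_BACKGROUND: {ROOT_TERM},
        BACKGROUND_TERM: {MID_BACKGROUND},
    }
    for t, term in enumerate(module_terms):
        parents[term] = {MID_STIMULUS} if t % 2 == 0 else {MID_STIMULUS, ROOT_TERM}
    obo_path = out_dir / "go.obo"
    _write_obo(obo_path, module_terms)

    # --- annotations ------------------------------------------------------
    direct: list[tuple[str, str, str]] = []  # (gene, term, evidence)
    for term in module_terms:
        for g in module_genes[term]:
            direct.append((g, term, str(rng.choice(_EVIDENCE_CODES))))
    for g in gene_ids:
        direct.append((g, BACKGROUND_TERM, "IEA"))
    for g in gene_ids[:3]:
        direct.append((g, MF_TERM, "IEA"))  # exercises namespace filtering
    gaf_path = out_dir / "annotations.gaf"
    _write_gaf(gaf_path, sorted(direct))

    # --- genome annotation and gene lists ---------------------------------
    gff_path = out_dir / "genome.gff3"
    with open(gff_path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in sorted(genes, key=lambda x: (x["chrom"], x["start1"])):
            fh.write(
                f"{g['chrom']}\tsynthetic\tgene\t{g['start1']}\t{g['end1']}\t.\t"
                f"{g['strand']}\t.\tID={g['gene_id']}\n"
            )
    udegs_path = _write_list(out_dir / "udegs.txt", udegs)
    ddegs_path = _write_list(out_dir / "ddegs.txt", ddegs)
    degs_path = _write_list(out_dir / "degs.txt", sorted(set(udegs) | set(ddegs)))
    _write_list(out_dir / "tfs.txt", tf_ids)

    # --- truth ------------------------------------------------------------
    truth = _expected_outcome(
        spec, parents, module_terms, module_genes, direct,
        gene_ids, tf_ids, udegs, ddegs, truth_pairs, planted,
    )
    _write_truth(out_dir, truth)
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump({
            "spec": asdict(spec),
            "tf_ids": tf_ids,
            "module_terms": module_terms,
        }, fh, indent=2, default=list)

    return FixtureBundle(
        out_dir=out_dir, gff_path=gff_path, peaks_meta=peaks_meta,
        peaks_dir=peaks_dir, obo_path=obo_path, gaf_path=gaf_path,
        udegs_path=udegs_path, ddegs_path=ddegs_path, degs_path=degs_path,
        tf_ids=tf_ids, tf_families=tf_families,
        module_terms=module_terms, module_genes=module_genes,
        udegs=udegs, ddegs=ddegs, planted=planted,
        truth_pairs=truth_pairs, **truth,
    )


def _expected_outcome(spec, parents, module_terms, module_genes, direct,
                      gene_ids, tf_ids, udegs, ddegs, truth_pairs, planted) -> dict:
    """Exact expected analysis outcome from generator bookkeeping.

    Re-derives the contingency counts by direct set arithmetic over the
    objects the generator placed (no interval mapping, no file parsing, no
    ontology machinery), then applies the shared exact-test primitives.
    """
    # propagated BP annotation closure over the toy DAG
    closure: dict[str, set[str]] = {}
    for term in parents:
        seen, stack = set(), [term]
        while stack:
            t = stack.pop()
            if t in seen:
                continue
            seen.add(t)
            stack.extend(parents[t])
        closure[term] = seen
    gene_terms: dict[str, set[str]] = {}
    for g, term, _ev in direct:
        if term == MF_TERM:
            continue
        gene_terms.setdefault(g, set()).update(closure[term])

    universe = set(gene_terms)
    selection = sorted((set(udegs) | set(ddegs)) & universe)
    sel = set(selection)
    term_members: dict[str, set[str]] = {}
    for g in universe:
        for t in gene_terms[g]:
            term_members.setdefault(t, set()).add(g)
    tested = []
    for term in sorted(term_members):
        hits = term_members[term] & sel
        if len(hits) >= spec.min_term_size:
            c = EnrichmentCount(k=len(hits), n=len(selection), K=len(term_members[term]),
                                N=len(universe))
            tested.append((term, hits, hypergeom_pvalue(c)))
    adj = bh_adjust([(t, p) for t, _h, p in tested])
    truth_terms = {t for (t, _h, _p), a in zip(tested, adj) if a.q <= spec.go_fdr}
    term_hits = {t: h for t, h, _p in tested}

    # TF enrichment per direction over the same target pairs
    targets: dict[str, set[str]] = {}
    for tf, g in truth_pairs:
        targets.setdefault(tf, set()).add(g)
    truth_tfs: dict[str, set[str]] = {}
    for direction, degs in (("up", set(udegs)), ("down", set(ddegs))):
        fam = [(tf, EnrichmentCount(k=len(tg & degs), n=len(degs), K=len(tg), N=len(gene_ids)))
               for tf, tg in sorted(targets.items()) if tg]
        adj_tf = bh_adjust([(tf, hypergeom_pvalue(c)) for tf, c in fam])
        truth_tfs[direction] = {a.id for a in adj_tf if a.q <= spec.tf_fdr}

    enriched_tfs = truth_tfs["up"] | truth_tfs["down"]
    truth_links = {
        (tf, g, term)
        for term in truth_terms
        for g in term_hits[term]
        for tf in enriched_tfs
        if (tf, g) in truth_pairs
    }
    deg_status = {tf: ("up" if tf in set(udegs) else "down" if tf in set(ddegs) else "none")
                  for tf in tf_ids}
    truth_types = {}
    for tf in sorted(enriched_tfs):
        dirs = [d for d in ("up", "down") if tf in truth_tfs[d]]
        truth_types[tf] = ",".join(
            classify_regulation(tf, d, deg_status[tf]).value for d in dirs)
    truth_edges = {
        (a, b) for a in enriched_tfs for b in enriched_tfs if (a, b) in truth_pairs
    }
    return {
        "truth_tfs": truth_tfs,
        "truth_terms": truth_terms,
        "truth_links": truth_links,
        "truth_types": truth_types,
        "truth_edges": truth_edges,
    }


def _write_bed(path, rows) -> None:
    with open(path, "w") as fh:
        for chrom, s, e in rows:
            fh.write(f"{chrom}\t{s}\t{e}\n")


def _write_list(path, items) -> Path:
    with open(path, "w") as fh:
        for it in items:
            fh.write(f"{it}\n")
    return Path(path)


def _write_obo(path, module_terms) -> None:
    stanzas = [
        (ROOT_TERM, "biological process root", "biological_process", [], []),
        (MID_STIMULUS, "response to stimulus", "biological_process", [ROOT_TERM], []),
        (MID_BACKGROUND, "cellular maintenance", "biological_process", [ROOT_TERM], []),
        (BACKGROUND_TERM, "housekeeping process", "biological_process", [MID_BACKGROUND], []),
        (MF_TERM, "generic binding", "molecular_function", [], []),
    ]
    for t, term in enumerate(module_terms):
        is_a = [MID_STIMULUS]
        part_of = [] if t % 2 == 0 else [ROOT_TERM]
        stanzas.append((term, f"planted process {t + 1}", "biological_process", is_a, part_of))
    with open(path, "w") as fh:
        fh.write("format-version: 1.2\nontology: synthetic-toy-go\n")
        for tid, name, ns, is_a, part_of in stanzas:
            fh.write(f"\n[Term]\nid: {tid}\nname: {name}\nnamespace: {ns}\n")
            for p in is_a:
                fh.write(f"is_a: {p}\n")
            for p in part_of:
                fh.write(f"relationship: part_of {p}\n")
        fh.write("\n[Term]\nid: GO:0000999\nname: retired process\n"
                 "namespace: biological_process\nis_obsolete: true\n")
        fh.write("\n[Typedef]\nid: part_of\nname: part of\n")


def _write_gaf(path, rows) -> None:
    with open(path, "w") as fh:
        fh.write("!gaf-version: 2.2\n")
        for g, term, ev in rows:
            aspect = "F" if term == MF_TERM else "P"
            cols = ["SYN", g, g, "", term, "SYN:0000001", ev, "", aspect,
                    "", "", "gene", "taxon:3702", "20240101", "SYN", "", ""]
            fh.write("\t".join(cols) + "\n")


def _write_truth(out_dir: Path, truth: dict) -> None:
    with open(out_dir / "truth_links.tsv", "w") as fh:
        fh.write("tf_id\tgene_id\tterm_id\n")
        for tf, g, term in sorted(truth["truth_links"]):
            fh.write(f"{tf}\t{g}\t{term}\n")
    with open(out_dir / "truth_types.tsv", "w") as fh:
        fh.write("tf_id\tregulation_type\n")
        for tf, typ in sorted(truth["truth_types"].items()):
            fh.write(f"{tf}\t{typ}\n")
    with open(out_dir / "truth_terms.tsv", "w") as fh:
        fh.write("term_id\n")
        for term in sorted(truth["truth_terms"]):
            fh.write(f"{term}\n")
    with open(out_dir / "truth_edges.tsv", "w") as fh:
        fh.write("regulator\ttarget\n")
        for a, b in sorted(truth["truth_edges"]):
            fh.write(f"{a}\t{b}\n")
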