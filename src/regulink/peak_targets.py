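"""TF binding-peak collections and peak-to-promoter target mapping.

A peak collection is a set of BED files (one per peak set) plus a metadata
table describing which TF each set profiles and under what sample
conditions (tissue, DNA methylation state, assay, ...). Mapping peaks onto
5' regulatory regions yields the TF -> target-gene assignment that every
downstream stage (TF enrichment, network reconstruction, process linking)
consumes. A gene is a target of a TF when any peak from any of the TF's
peak sets overlaps the gene's regulatory region by at least ``min_overlap_bp``
(default 1 bp); multiple peak sets of the same TF are unioned.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from intervaltree import IntervalTree

from .annotation_io import RegulatoryRegion
from .errors import ChromosomeMismatchError, DuplicateIdError, ParseError

__all__ = ["Peak", "PeakSet", "TargetMap", "load_collection", "filter_collection",
           "map_targets", "read_bed_peaks"]

_META_REQUIRED = ("set_id", "tf_id", "tf_family")


@dataclass(frozen=True, order=True)
class Peak:
    """A called binding interval, 0-based half-open, unstranded."""

    chrom: str
    start: int
    end: int
    score: float | None = field(default=None, compare=False)

    def __post_init__(self):
        if self.start >= self.end:
            raise ValueError(f"peak {self.chrom}:{self.start}-{self.end}: start must be < end")


@dataclass
class PeakSet:
    """One TF's peaks from one profiling experiment, with sample metadata."""

    set_id: str
    tf_id: str
    tf_family: str
    sample_meta: dict[str, str]
    peaks: list[Peak]

    def __post_init__(self):
        if not self.tf_id:
            raise ValueError(f"peak set {self.set_id}: tf_id must be non-empty")


class TargetMap:
    """TF -> target-gene assignments with supporting peak evidence.

    ``entries`` maps (tf_id, gene_id) to the sorted list of peaks that
    overlap the gene's regulatory region.
    """

    def __init__(self, entries: Mapping[tuple[str, str], list[Peak]] | None = None):
        self.entries: dict[tuple[str, str], list[Peak]] = dict(entries or {})

    def __contains__(self, key: tuple[str, str]) -> bool:
        return key in self.entries

    def __len__(self) -> int:
        return len(self.entries)

    def pairs(self) -> set[tuple[str, str]]:
        return set(self.entries)

    def targets_of(self, tf_id: str) -> set[str]:
        return {g for (t, g) in self.entries if t == tf_id}

    def tfs(self) -> set[str]:
        return {t for (t, _g) in self.entries}

    def restrict_tfs(self, tf_ids: Iterable[str]) -> "TargetMap":
        """The sub-map containing only the given TFs."""
        keep = set(tf_ids)
        return TargetMap({k: v for k, v in self.entries.items() if k[0] in keep})

    def to_frame(self) -> pd.DataFrame:
        """Flat table: one row per (tf, gene, supporting peak)."""
        rows = [
            (tf, gene, p.chrom, p.start, p.end)
            for (tf, gene), peaks in sorted(self.entries.items())
            for p in peaks
        ]
        return pd.DataFrame(rows, columns=["tf_id", "gene_id", "peak_chrom", "peak_start", "peak_end"])

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def read_bed_peaks(path) -> list[Peak]:
    """Parse a BED3+ file into peaks (column 5, if present, is the score)."""
    peaks = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError("expected at least 3 BED columns", path=path, line_number=lineno)
            chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            if start >= end:
                raise ParseError(f"interval start {start} >= end {end}", path=path, line_number=lineno)
            score = None
            if len(fields) >= 5 and fields[4] not in (".", ""):
                score = float(fields[4])
            peaks.append(Peak(chrom, start, end, score))
    return peaks


def load_collection(metadata_table, bed_dir) -> list[PeakSet]:
    """Load a peak collection from a metadata TSV plus a directory of BEDs.

    The table needs columns ``set_id``, ``tf_id``, ``tf_family``; every
    other column becomes a sample-metadata key. Each ``set_id`` resolves to
    ``<bed_dir>/<set_id>.bed`` unless a ``bed_file`` column names the file
    explicitly. A missing BED raises an error naming the set_id; an empty
    BED yields a valid zero-peak set.
    """
    bed_dir = Path(bed_dir)
    meta = pd.read_csv(metadata_table, sep="\t", dtype=str).fillna("")
    for col in _META_REQUIRED:
        if col not in meta.columns:
            raise ParseError(f"metadata table lacks required column {col!r}", path=metadata_table)
    dupes = meta["set_id"][meta["set_id"].duplicated()].tolist()
    if dupes:
        raise DuplicateIdError(f"duplicate set_id values in metadata: {sorted(set(dupes))}")
    meta_cols = [c for c in meta.columns if c not in _META_REQUIRED and c != "bed_file"]
    collection = []
    for row in meta.itertuples(index=False):
        rec = row._asdict()
        bed_name = rec.get("bed_file") or f"{rec['set_id']}.bed"
        bed_path = bed_dir / bed_name
        if not bed_path.exists():
            raise FileNotFoundError(f"peak set {rec['set_id']!r}: BED file not found: {bed_path}")
        sample_meta = {c: rec[c] for c in meta_cols if rec[c] != ""}
        collection.append(PeakSet(
            set_id=rec["set_id"],
            tf_id=rec["tf_id"],
            tf_family=rec["tf_family"],
            sample_meta=sample_meta,
            peaks=read_bed_peaks(bed_path),
        ))
    return collection


def filter_collection(collection: Iterable[PeakSet], criteria: Mapping[str, str]) -> list[PeakSet]:
    """Keep peak sets whose sample_meta matches every criteria key=value; order preserved."""
    return [
        ps for ps in collection
        if all(ps.sample_meta.get(k) == v for k, v in criteria.items())
    ]


def map_targets(collection: Iterable[PeakSet],
                regions: Mapping[str, RegulatoryRegion] | Iterable[RegulatoryRegion],
                min_overlap_bp: int = 1) -> TargetMap:
    """Assign target genes to TFs by peak/promoter overlap.

    (tf, gene) is recorded iff some peak of some peak set of that TF
    overlaps the gene's regulatory region by >= ``min_overlap_bp``; the
    supporting peaks are kept. Peak strand is ignored. Raises
    :class:`ChromosomeMismatchError` when peaks and regions exist but share
    no chromosome name at all (the symptom of mismatched naming
    conventions, e.g. 'chr1' vs '1'); names are never normalised.
    """
    if min_overlap_bp < 1:
        raise ValueError(f"min_overlap_bp must be >= 1, got {min_overlap_bp}")
    if isinstance(regions, Mapping):
        regions = list(regions.values())
    else:
        regions = list(regions)
    gene_ids = [r.gene_id for r in regions]
    if len(set(gene_ids)) != len(gene_ids):
        raise DuplicateIdError("regions must reference distinct gene_ids")

    trees: dict[str, IntervalTree] = {}
    for r in regions:
        if len(r) == 0:
            continue  # fully clipped region cannot overlap anything
        trees.setdefault(r.chrom, IntervalTree()).addi(r.start, r.end, r.gene_id)

    collection = list(collection)
    region_chroms = {r.chrom for r in regions}
    peak_chroms = {p.chrom for ps in collection for p in ps.peaks}
    if peak_chroms and region_chroms and not (peak_chroms & region_chroms):
        raise ChromosomeMismatchError(peak_chroms, region_chroms)

    entries: dict[tuple[str, str], set[Peak]] = {}
    for ps in collection:
        for peak in ps.peaks:
            tree = trees.get(peak.chrom)
            if tree is None:
                continue
            for iv in tree.overlap(peak.start, peak.end):
                if min(peak.end, iv.end) - max(peak.start, iv.begin) >= min_overlap_bp:
                    entries.setdefault((ps.tf_id, iv.data), set()).add(peak)
    return TargetMap({k: sorted(v) for k, v in entries.items()})
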