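"""Genome annotation parsing and strand-aware 5' regulatory regions.

A gene's 5' regulatory region (promoter window) is the fixed-length stretch
immediately upstream of its transcription start site (TSS), on the gene's
own strand. GFF3 gene records are 1-based inclusive; every internal interval
and every BED record is 0-based half-open — the conversion happens here, at
the parse and write boundaries, and nowhere else.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import gffutils.feature

from .errors import DuplicateIdError, ParseError

__all__ = [
    "GeneModel",
    "RegulatoryRegion",
    "parse_gff3",
    "regulatory_region",
    "regions_for_genes",
    "write_regions_bed",
    "read_regions_bed",
]

#: Promoter window lengths (bp) exposed by the command-line interface.
STANDARD_UPSTREAM_LENGTHS = (500, 1000, 1500, 2000, 2500)

DEFAULT_UPSTREAM_LENGTH = 1000


@dataclass(frozen=True)
class GeneModel:
    """A gene's genomic placement at gene-level granularity.

    Coordinates are 1-based inclusive as in GFF3. The TSS is derived from
    the gene feature's 5'-most coordinate: ``start`` on the '+' strand,
    ``end`` on the '-' strand. No transcript isoforms are modelled.
    """

    gene_id: str
    chrom: str
    strand: str
    start: int
    end: int
    symbol: str | None = None
    family: str | None = None

    def __post_init__(self):
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: strand must be '+' or '-', got {self.strand!r}")
        if self.start > self.end:
            raise ValueError(f"gene {self.gene_id}: start {self.start} > end {self.end}")
        if self.start < 1:
            raise ValueError(f"gene {self.gene_id}: coordinates are 1-based, got start {self.start}")

    @property
    def tss(self) -> int:
        """1-based transcription start position (start on '+', end on '-')."""
        return self.start if self.strand == "+" else self.end


@dataclass(frozen=True)
class RegulatoryRegion:
    """A promoter window as a 0-based half-open interval.

    The interval abuts the TSS and extends ``requested_length`` bp upstream
    with respect to gene strand; it may be shorter after clipping at
    chromosome position 0.
    """

    gene_id: str
    chrom: str
    start: int
    end: int
    requested_length: int
    strand: str = "."

    def __post_init__(self):
        if self.start < 0 or self.end < self.start:
            raise ValueError(
                f"region for {self.gene_id}: invalid interval [{self.start}, {self.end})"
            )
        if self.end - self.start > self.requested_length:
            raise ValueError(
                f"region for {self.gene_id}: length {self.end - self.start} exceeds "
                f"requested {self.requested_length}"
            )

    def __len__(self) -> int:
        return self.end - self.start


def parse_gff3(path) -> dict[str, GeneModel]:
    """Parse GFF3 ``gene`` records into a mapping gene_id -> GeneModel.

    Only features of type ``gene`` are read; they must carry an ``ID``
    attribute. Raises :class:`ParseError` (with the line number) on a
    malformed line and :class:`DuplicateIdError` on a repeated gene ID.
    """
    genes: dict[str, GeneModel] = {}
    path = Path(path)
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ParseError(
                    f"expected 9 tab-separated columns, got {len(fields)}",
                    path=path, line_number=lineno,
                )
            if fields[2] != "gene":
                continue
            try:
                feat = gffutils.feature.feature_from_line(line)
            except Exception as exc:  # gffutils raises several types
                raise ParseError(str(exc), path=path, line_number=lineno) from exc
            if "ID" not in feat.attributes:
                raise ParseError("gene record lacks an ID attribute", path=path, line_number=lineno)
            gene_id = feat.attributes["ID"][0]
            if gene_id in genes:
                raise DuplicateIdError(f"duplicate gene ID {gene_id!r} at line {lineno} of {path}")
            if feat.strand not in ("+", "-"):
                raise ParseError(
                    f"gene {gene_id}: strand must be '+' or '-', got {feat.strand!r}",
                    path=path, line_number=lineno,
                )
            symbol = feat.attributes["Name"][0] if "Name" in feat.attributes else None
            genes[gene_id] = GeneModel(
                gene_id=gene_id,
                chrom=feat.seqid,
                strand=feat.strand,
                start=feat.start,
                end=feat.end,
                symbol=symbol,
            )
    return genes


def regulatory_region(gene: GeneModel, length: int = DEFAULT_UPSTREAM_LENGTH) -> RegulatoryRegion:
    """The ``length``-bp window immediately upstream of the gene's TSS.

    On '+' the window is [tss-1-length, tss-1) in 0-based half-open
    coordinates (positions tss-length .. tss-1 in 1-based terms); on '-'
    upstream runs genomically rightward, giving [tss, tss+length). Windows
    reaching past the chromosome origin are clipped at 0; no right-edge
    clipping is applied (chromosome lengths are not required).
    """
    if length <= 0:
        raise ValueError(f"upstream length must be positive, got {length}")
    if gene.strand == "+":
        end = gene.tss - 1
        start = max(0, end - length)
    else:
        start = gene.tss
        end = start + length
    return RegulatoryRegion(
        gene_id=gene.gene_id,
        chrom=gene.chrom,
        start=start,
        end=end,
        requested_length=length,
        strand=gene.strand,
    )


def regions_for_genes(genes: Iterable[GeneModel] | dict[str, GeneModel],
                      length: int = DEFAULT_UPSTREAM_LENGTH) -> dict[str, RegulatoryRegion]:
    """Promoter windows for every gene, keyed by gene_id."""
    if isinstance(genes, dict):
        genes = genes.values()
    return {g.gene_id: regulatory_region(g, length) for g in genes}


def write_regions_bed(regions: Iterable[RegulatoryRegion], path) -> None:
    """Write regions as BED6 (name=gene_id), sorted by (chrom, start, end, name)."""
    rows = sorted(regions, key=lambda r: (r.chrom, r.start, r.end, r.gene_id))
    with open(path, "w") as fh:
        for r in rows:
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.gene_id}\t.\t{r.strand}\n")


def read_regions_bed(path, requested_length: int | None = None) -> list[RegulatoryRegion]:
    """Reparse a BED6 file written by :func:`write_regions_bed`."""
    out = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise ParseError("expected 6 BED columns", path=path, line_number=lineno)
            chrom, start, end, name, _score, strand = fields[:6]
            start, end = int(start), int(end)
            out.append(RegulatoryRegion(
                gene_id=name, chrom=chrom, start=start, end=end,
                requested_length=requested_length if requested_length is not None else end - start,
                strand=strand,
            ))
    return out
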