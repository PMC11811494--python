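"""Map TF binding peaks onto promoter windows to call target genes.

A gene is a target when any peak of any of the TF's peak sets overlaps its
regulatory region by at least 1 bp; peak sets of one TF are unioned.
"""

from regulink import GeneModel, Peak, PeakSet, map_targets, regions_for_genes

genes = {
    "gA": GeneModel("gA", "chr1", "+", 2001, 3000),   # promoter [1000, 2000)
    "gB": GeneModel("gB", "chr1", "-", 5001, 6000),   # promoter [6000, 7000)
    "gC": GeneModel("gC", "chr2", "+", 2001, 3000),
}
regions = regions_for_genes(genes, length=1000)

collection = [
    PeakSet("set1", "TF1", "WRKY", {"tissue": "leaf"},
            [Peak("chr1", 1900, 2100),    # overlaps gA's promoter by 100 bp
             Peak("chr1", 6900, 7100)]),  # overlaps gB's promoter
    PeakSet("set2", "TF2", "MYB", {"tissue": "leaf"},
            [Peak("chr1", 900, 1000)]),   # abuts gA's promoter: no overlap
]

tm = map_targets(collection, regions)
for (tf, gene), peaks in sorted(tm.entries.items()):
    spans = ", ".join(f"{p.chrom}:{p.start}-{p.end}" for p in peaks)
    print(f"{tf} -> {gene}  (supported by {spans})")
print(f"TF2 targets: {sorted(tm.targets_of('TF2')) or 'none'} "
      "(half-open abutment does not count as overlap)")
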