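"""Derive strand-aware 5' regulatory regions from gene coordinates.

The regulatory window abuts the transcription start site and extends a
fixed number of bp upstream on the gene's own strand, so on '-' genes it
runs genomically rightward from the gene end.
"""

from regulink import GeneModel, regulatory_region

plus = GeneModel("AT1G00010", "chr1", "+", start=5001, end=7000)
minus = GeneModel("AT1G00020", "chr1", "-", start=9001, end=11000)

for gene in (plus, minus):
    for length in (500, 1000, 2500):
        r = regulatory_region(gene, length)
        print(f"{gene.gene_id} ({gene.strand}) TSS={gene.tss:>6} "
              f"upstream={length:>4} -> [{r.start}, {r.end}) ({len(r)} bp)")

clipped = regulatory_region(GeneModel("AT1G00030", "chr1", "+", 301, 800), 1000)
print(f"near the origin the window is clipped: [{clipped.start}, {clipped.end}) "
      f"({len(clipped)} of 1000 bp requested)")
# Each line shows the 0-based half-open promoter interval used for peak
# overlap; the TSS base itself is never inside the window.
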