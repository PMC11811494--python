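"""GO over-representation of a gene selection with annotation propagation.

Ten genes form the universe; four are annotated to a leaf process. A
selection of five genes hitting three of the four gives the classic
one-sided hypergeometric p = 66/252.
"""

from regulink import GeneAnnotation, func_annot
from regulink.go_annot import GOTerm, Ontology

ontology = Ontology([
    GOTerm("GO:0000001", "biological process root", "biological_process", frozenset()),
    GOTerm("GO:0000002", "response to stimulus", "biological_process",
           frozenset({"GO:0000001"})),
    GOTerm("GO:0000003", "response to salt", "biological_process",
           frozenset({"GO:0000002"})),
])

annotation = GeneAnnotation()
genes = [f"g{i}" for i in range(10)]
for g in genes:
    annotation.add(g, "GO:0000001", "IEA")       # everything in the universe
for g in genes[:4]:
    annotation.add(g, "GO:0000003", "IDA")       # four genes in the leaf term

selection = ["g0", "g1", "g2", "g5", "g6"]       # 3 of 5 hit the leaf term
results = func_annot(selection, annotation, ontology, alpha=1.0)
for r in results:
    print(f"{r.term_id} {r.name:<28} k={r.counts.k} K={r.counts.K} "
          f"n={r.counts.n} N={r.counts.N}  p={r.p:.6f} q={r.q:.6f}")
    print("   genes:", ", ".join(f"{g}[{'|'.join(sorted(ev))}]" for g, ev in r.genes))
# The leaf term's p (0.261905 = 66/252) propagates identically to its
# parent because the same three genes carry both terms after closure.
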