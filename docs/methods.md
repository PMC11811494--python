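# Methods

## Scope and model

`regulink` connects three standard objects — DEG lists, a TF binding-peak
collection, and GO annotations — into regulatory links (TF, target gene,
enriched process) and a typed TF–TF network. It consumes peaks as called
intervals and DEG lists as given: peak calling and differential-expression
testing are upstream of this package, as is any biological interpretation
of the output.

## Coordinates and promoters

GFF3 gene records are 1-based inclusive; every internal interval and every
BED file is 0-based half-open, with conversion only at parse/write
boundaries. The transcription start is taken at gene granularity: the gene
feature's 5′-most coordinate (start on '+', end on '−'). No transcript
isoforms, UTR-aware promoter definitions or accessibility masks are
modelled. The 5′ regulatory region of length L abuts the TSS: on '+' it is
`[tss−1−L, tss−1)`, on '−' `[tss, tss+L)`. Windows are clipped at position
0; the right edge is never clipped because chromosome lengths are not
required (peaks define the usable extent). Windows of neighbouring or
overlapping genes are computed independently, so one peak may support
several genes — promoter sharing is deliberately not deduplicated, and
regions are not truncated at upstream gene boundaries.

L is exposed as `upstream_length`: the CLI restricts it to
{500, 1000, 1500, 2000, 2500} with default 1000; the library accepts any
positive integer.

## Target calling

A gene is a target of a TF when any peak from any of the TF's peak sets
overlaps the gene's window by at least `min_overlap_bp` (default 1 bp).
The 1-bp criterion is the weakest defensible reading of "peak mapped to
the regulatory region"; requiring summit or midpoint containment would be
stricter, and the knob exists for users who want a larger minimum overlap.
Peak strand is ignored; multiple peak sets of one TF are unioned because
downstream results are reported per TF, not per experiment. Chromosome
names are never normalised: if the peaks and the annotation share no
chromosome name at all, mapping aborts with an error listing both name
sets (the classic `chr1` vs `1` failure); partially disjoint naming is
allowed, since an annotation may legitimately cover fewer chromosomes
than a genome-wide peak collection. Interval queries go through an
interval tree; correctness is established against quadratic all-pairs
scans in the tests.

## Enrichment statistics

Both enrichment stages use the one-sided hypergeometric upper tail
P(X ≥ k) — equivalently a one-sided Fisher exact test — computed via
scipy's log-space survival function. The package treats one-sided
over-representation as the canonical reading for both promoter and GO
enrichment; no mid-p or continuity correction is applied. Multiple testing
uses Benjamini–Hochberg step-up: q(i) = min over j ≥ i of min(1, p(j)·m/j),
implemented directly so that tie and ordering semantics are pinned (equal
p ⇒ equal q; output in input order; ties iterated in id order, which
cannot affect q). The test suite validates the tail against exhaustive
draw enumeration on the complete N ≤ 12 grid and the adjustment against a
naive O(m²) reference.

TF enrichment counts *target genes*, not peaks (one gene = one Bernoulli
trial); its universe is every gene with a defined regulatory region — not
only expressed genes — because the peak collections are genome-wide and
the background should match them. Up- and down-regulated DEG lists form
separate BH families (default `tf_fdr` 0.001). TFs with zero targets in
the universe are skipped and logged rather than assigned p = 1, keeping
the BH family to informative tests.

GO enrichment propagates annotations up the DAG over is_a and part_of
(the true-path rule), carrying evidence codes unchanged. The universe
defaults to genes with ≥ 1 propagated annotation in the chosen namespace
(the convention of the widely used R ORA tooling), overridable explicitly.
Defaults: namespace biological_process, `go_fdr` 0.05, `min_term_size` 2
selection hits, no maximum term size. Evidence codes (including IEA) are
reported and never filtered. No GSEA mode, no conditional/elim-style
testing, no term-reduction post-processing.

## Regulation types and the network

A TF enriched in uDEG promoters and itself upregulated is a UA
(upregulated activator: induced by the stimulus, drives its targets up);
enriched in dDEG promoters and upregulated, a US (induced suppressor);
enriched in dDEG promoters and downregulated, a DA (the stimulus represses
the activator, so its targets fall); enriched in uDEG promoters and
downregulated, a DS (the stimulus represses the suppressor, releasing its
targets). A consequence worth noting: a network built solely from
up-enriched TFs can only contain UA, DS and untyped nodes. TFs that are
not DEGs are included as `untyped` by default (`include_untyped=False`
drops them); a TF enriched in both directions keeps one node with both
labels. Edges are exactly the target map restricted to TF-encoding genes
under the same peak-set metadata filter as target mapping; self-loops (a
TF binding its own promoter) are retained and flagged. Hubs rank by total
degree (in + out, self-loops counted once), ties sharing a rank with
lexicographic ordering for determinism; in- and out-degree are reported
separately as well.

## Output blocks

Blocks 1–4 are four groupings of one link set (by gene, by process, by
TF, flat); block 5 is the raw GO table. Genes of an enriched process with
zero candidate TFs stay in blocks 1–2 with TF count 0 — the per-gene TF
count is part of the contract. List cells are comma-separated and sorted,
families in parentheses, evidence codes pipe-separated; all tables are
deterministically sorted so identical inputs yield byte-identical files.
Column order within blocks is this package's own choice; content coverage
is the contract.

## Synthetic data generator

The generator emulates a stimulus-response study at desk scale: by
default 400 genes on 2 chromosomes, 10 TFs, two 40-gene modules (one
up-, one down-regulated), each module annotated to one leaf term of a
depth-3 GO DAG (with part_of edges present to exercise propagation, an
obsolete term, and one molecular_function term to exercise namespace
filtering), DEG lists holding 12 % of genes per direction (modules plus
random fill), and two planted regulators on the up-module — one UA, one
DS, coverage 0.8 of module promoters — over background binding with
per-gene probability 0.1, the regime in which a response that begins with
transcriptional activation yields a UA/DS network. Peak sets carry
leaf/methylated/dap-seq metadata, plus decoy unmethylated sets that the
metadata filter must remove. Genes sit on fixed-width slots wide enough
that promoter windows can never overlap or clip, so target calling is
unambiguous by construction.

Because the generator knows every peak it placed and every gene it drew,
it derives truth tables (target pairs, enriched TFs and terms, links,
regulation types, network edges) from its own set arithmetic — an
independent bookkeeping path from the pipeline's parsers, interval trees
and joins, though it shares the exact-test primitives, which are
themselves validated against enumeration oracles. What passing recovery
tests show is therefore that the machinery reconstructs exactly what was
planted under the stated noise; they do not show robustness to features
of real data the generator omits: overlapping genes and shared promoters,
transcript-level TSS variation, non-uniform background binding, peak-width
and score distributions, incomplete or biased GO annotation, and DEG
miscalls.

A single seeded generator stream drives all draws; a manifest records the
parameters. Bundles are byte-identical across runs at the same seed.

## Problem sizes and numerics

The recovery study uses 100 seeded replicates at the default conditions
(400 genes, 10 TFs), chosen so that the planted effects are comfortably
detectable by the exact test at the stated thresholds while the whole
study remains a desk-scale computation. Oracle-equivalence checks use
universes up to 200 genes (exact fractions) and the complete enumeration
grid up to N = 12. P-values deep in the tail may underflow double
precision below ~1e-308; enrichment decisions compare against thresholds
far above that. Ties everywhere break lexicographically for reproducible
output.

## Known limitations

Gene-level TSS only; no promoter truncation by neighbouring genes; no
motif analysis or peak re-processing; enrichment is purely interval-based;
the hypergeometric reading of "enrichment" is an interpretation where the
upstream tooling does not document its statistic; no web interface or
interactive visualisation.
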