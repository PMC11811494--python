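import numpy as np
import pytest

from _oracles import dfs_closure, frac_hypergeom_tail, naive_bh
from regulink.errors import NoAnnotatedGenesError, ParseError
from regulink.go_annot import (GeneAnnotation, GOTerm, Ontology, func_annot,
                               parse_gaf, parse_obo, propagate)


@pytest.fixture
def toy_ontology(tmp_path, toy_ontology_text):
    p = tmp_path / "toy.obo"
    p.write_text(toy_ontology_text)
    return parse_obo(p)


class TestParseObo:
    def test_chain_parentage(self, toy_ontology):
        assert toy_ontology["GO:0000002"].parents == {"GO:0000001"}
        assert toy_ontology.ancestors("GO:0000003") == {"GO:0000001", "GO:0000002"}

    def test_is_a_and_part_of_both_captured(self, toy_ontology):
        assert toy_ontology["GO:0000003"].parents == {"GO:0000001", "GO:0000002"}

    def test_obsolete_flagged_and_out_of_dag(self, toy_ontology):
        assert toy_ontology["GO:0000009"].obsolete
        assert "GO:0000009" not in toy_ontology.namespace_terms("biological_process")

    def test_cycle_detected(self):
        with pytest.raises(Exception, match="cycle"):
            Ontology([
                GOTerm("a", "a", "biological_process", frozenset({"b"})),
                GOTerm("b", "b", "biological_process", frozenset({"a"})),
            ])

    def test_unknown_parent_rejected(self):
        with pytest.raises(ParseError, match="unknown parent"):
            Ontology([GOTerm("a", "a", "biological_process", frozenset({"zzz"}))])


class TestParseGaf:
    def _gaf(self, tmp_path, rows):
        p = tmp_path / "a.gaf"
        lines = ["!gaf-version: 2.2"]
        for gene, term, ev, qual in rows:
            cols = ["DB", gene, gene, qual, term, "REF:1", ev, "", "P", "", "",
                    "gene", "taxon:3702", "20240101", "DB", "", ""]
            lines.append("\t".join(cols))
        p.write_text("\n".join(lines) + "\n")
        return p

    def test_direct_annotation_with_evidence(self, tmp_path):
        ann = parse_gaf(self._gaf(tmp_path, [("g1", "GO:0000003", "IDA", "")]))
        assert ann.terms_of("g1") == {"GO:0000003": {"IDA"}}

    def test_duplicate_rows_union_evidence(self, tmp_path):
        ann = parse_gaf(self._gaf(tmp_path, [
            ("g1", "GO:0000003", "IDA", ""), ("g1", "GO:0000003", "IEA", "")]))
        assert ann.terms_of("g1")["GO:0000003"] == {"IDA", "IEA"}

    def test_not_qualified_rows_dropped(self, tmp_path):
        ann = parse_gaf(self._gaf(tmp_path, [
            ("g1", "GO:0000003", "IDA", "NOT|involved_in"),
            ("g2", "GO:0000003", "IDA", "involved_in")]))
        assert "g1" not in ann.genes() and "g2" in ann.genes()

    def test_truncated_row_names_line(self, tmp_path):
        p = tmp_path / "bad.gaf"
        p.write_text("!gaf-version: 2.2\nDB\tg1\tonly-three\n")
        with pytest.raises(ParseError, match="line 2"):
            parse_gaf(p)


class TestPropagate:
    def test_chain_closure_carries_evidence(self, toy_ontology):
        ann = GeneAnnotation({"g1": {"GO:0000003": {"IDA"}}})
        prop = propagate(ann, toy_ontology)
        assert set(prop.terms_of("g1")) == {"GO:0000001", "GO:0000002", "GO:0000003"}
        assert all(ev == {"IDA"} for ev in prop.terms_of("g1").values())

    def test_root_annotation_unchanged(self, toy_ontology):
        ann = GeneAnnotation({"g1": {"GO:0000001": {"IEA"}}})
        assert propagate(ann, toy_ontology).terms_of("g1") == {"GO:0000001": {"IEA"}}

    def test_matches_dfs_closure_on_random_dags(self):
        """50 random DAGs: propagation equals per-gene DFS ancestor closure."""
        rng = np.random.default_rng(42)
        for _ in range(50):
            n = int(rng.integers(3, 15))
            ids = [f"T{i}" for i in range(n)]
            parents = {ids[i]: set(rng.choice(ids[:i], size=min(i, int(rng.integers(0, 3))),
                                              replace=False))
                       for i in range(n)}  # edges only to earlier ids: acyclic
            onto = Ontology([GOTerm(t, t, "biological_process", frozenset(parents[t]))
                             for t in ids])
            genes = {f"g{j}": set(rng.choice(ids, size=int(rng.integers(1, 4)), replace=False))
                     for j in range(5)}
            ann = GeneAnnotation({g: {t: {"IEA"} for t in ts} for g, ts in genes.items()})
            prop = propagate(ann, onto)
            for g, ts in genes.items():
                expected = set().union(*({t} | dfs_closure(parents, t) for t in ts))
                assert set(prop.terms_of(g)) == expected


class TestFuncAnnot:
    def _setup(self, toy_ontology):
        # universe of 10 genes; term GO:0000003 annotated to 4 of them
        ann = GeneAnnotation()
        genes = [f"g{i}" for i in range(10)]
        for g in genes:
            ann.add(g, "GO:0000001", "IEA")
        for g in genes[:4]:
            ann.add(g, "GO:0000003", "IDA")
        return genes, ann

    def test_worked_counts_and_pvalue(self, toy_ontology):
        genes, ann = self._setup(toy_ontology)
        selection = genes[:3] + genes[4:6]  # 5 genes, 3 in the term
        res = func_annot(selection, ann, toy_ontology, alpha=1.0)
        by_id = {r.term_id: r for r in res}
        r = by_id["GO:0000003"]
        assert (r.counts.k, r.counts.n, r.counts.K, r.counts.N) == (3, 5, 4, 10)
        assert r.p == pytest.approx(66 / 252, rel=1e-12)
        assert r.gene_ids == ("g0", "g1", "g2")

    def test_selection_equal_universe_all_p_one(self, toy_ontology):
        genes, ann = self._setup(toy_ontology)
        res = func_annot(genes, ann, toy_ontology, alpha=1.0)
        assert res and all(r.p == pytest.approx(1.0) for r in res)

    def test_namespace_restriction_excludes_mf(self, toy_ontology):
        genes, ann = self._setup(toy_ontology)
        for g in genes[:4]:
            ann.add(g, "GO:0000004", "IEA")  # molecular_function term
        res = func_annot(genes[:5], ann, toy_ontology, alpha=1.0)
        assert all(r.term_id != "GO:0000004" for r in res)

    def test_unannotated_selection_raises(self, toy_ontology):
        _genes, ann = self._setup(toy_ontology)
        with pytest.raises(NoAnnotatedGenesError):
            func_annot(["nope1", "nope2"], ann, toy_ontology)

    def test_reported_genes_are_selected_and_annotated(self, toy_ontology):
        genes, ann = self._setup(toy_ontology)
        res = func_annot(genes[:5], ann, toy_ontology, alpha=1.0)
        prop = propagate(ann, toy_ontology)
        for r in res:
            assert len(r.genes) == r.counts.k
            for g, ev in r.genes:
                assert g in genes[:5]
                assert r.term_id in prop.terms_of(g)
                assert ev == prop.terms_of(g)[r.term_id]

    @pytest.mark.parametrize("block", range(2))
    def test_matches_naive_reference_on_random_instances(self, block):
        """50 random instances/block vs a nested-loop exact-fraction reference."""
        rng = np.random.default_rng(7 + block)
        for _ in range(50):
            n_genes = int(rng.integers(20, 120))
            n_terms = int(rng.integers(2, 8))
            gene_ids = [f"g{i}" for i in range(n_genes)]
            term_ids = [f"GO:{i:07d}" for i in range(1, n_terms + 1)]
            onto = Ontology([GOTerm(t, t, "biological_process", frozenset())
                             for t in term_ids])
            ann = GeneAnnotation()
            membership = {}
            for t in term_ids:
                members = {g for g in gene_ids if rng.random() < 0.3}
                membership[t] = members
                for g in members:
                    ann.add(g, t, "IEA")
            annotated = sorted(set().union(*membership.values()) or set())
            if len(annotated) < 4:
                continue
            sel_size = int(rng.integers(2, max(3, len(annotated) // 2)))
            selection = list(rng.choice(annotated, size=sel_size, replace=False))
            try:
                res = func_annot(selection, ann, onto, alpha=1.0, min_term_size=1)
            except NoAnnotatedGenesError:
                continue
            # naive reference: loop over terms, exact-fraction tail, naive BH
            N = len(annotated)
            sel = set(selection)
            tested = []
            for t in sorted(term_ids):
                K = len(membership[t])
                k = len(membership[t] & sel)
                if K == 0 or k < 1:
                    continue
                tested.append((t, k, K, float(frac_hypergeom_tail(N, K, len(sel), k))))
            qs = naive_bh([p for (_t, _k, _K, p) in tested])
            expected = {t: (k, K, p, q) for (t, k, K, p), q in zip(tested, qs)}
            got = {r.term_id: r for r in res}
            assert set(got) == set(expected)
            for t, (k, K, p, q) in expected.items():
                assert got[t].counts.k == k and got[t].counts.K == K
                assert got[t].p == pytest.approx(p, rel=1e-9)
                assert got[t].q == pytest.approx(q, rel=1e-9)
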