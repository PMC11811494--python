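import numpy as np
import pytest

from _oracles import brute_overlap_pairs
from regulink.annotation_io import RegulatoryRegion
from regulink.errors import ChromosomeMismatchError, DuplicateIdError, ParseError
from regulink.peak_targets import (Peak, PeakSet, filter_collection,
                                   load_collection, map_targets)


def _region(gene, chrom, start, end):
    return RegulatoryRegion(gene_id=gene, chrom=chrom, start=start, end=end,
                            requested_length=end - start, strand="+")


def _set(set_id, tf, peaks, **meta):
    return PeakSet(set_id=set_id, tf_id=tf, tf_family="FAM", sample_meta=meta,
                   peaks=[Peak(*p) for p in peaks])


class TestLoadCollection:
    def _write(self, tmp_path, rows, beds):
        meta = tmp_path / "meta.tsv"
        meta.write_text("set_id\ttf_id\ttf_family\ttissue\tdna_state\n" +
                        "".join("\t".join(r) + "\n" for r in rows))
        for name, body in beds.items():
            (tmp_path / name).write_text(body)
        return meta

    def test_loads_one_set_per_row(self, tmp_path):
        meta = self._write(
            tmp_path,
            [("s1", "tfA", "WRKY", "leaf", "methylated"),
             ("s2", "tfB", "MYB", "root", "unmethylated")],
            {"s1.bed": "chr1\t10\t60\n", "s2.bed": ""},
        )
        coll = load_collection(meta, tmp_path)
        assert [ps.set_id for ps in coll] == ["s1", "s2"]
        assert coll[0].peaks == [Peak("chr1", 10, 60)]
        assert coll[1].peaks == []  # empty BED is a valid zero-peak set
        assert coll[0].sample_meta == {"tissue": "leaf", "dna_state": "methylated"}

    def test_missing_bed_names_the_set(self, tmp_path):
        meta = self._write(tmp_path, [("s1", "tfA", "WRKY", "leaf", "m")], {})
        with pytest.raises(FileNotFoundError, match="s1"):
            load_collection(meta, tmp_path)

    def test_duplicate_set_id_rejected(self, tmp_path):
        meta = self._write(
            tmp_path,
            [("s1", "tfA", "WRKY", "leaf", "m"), ("s1", "tfB", "MYB", "leaf", "m")],
            {"s1.bed": ""},
        )
        with pytest.raises(DuplicateIdError, match="s1"):
            load_collection(meta, tmp_path)

    def test_inverted_interval_rejected(self, tmp_path):
        meta = self._write(tmp_path, [("s1", "tfA", "WRKY", "leaf", "m")],
                           {"s1.bed": "chr1\t60\t10\n"})
        with pytest.raises(ParseError, match="line 1"):
            load_collection(meta, tmp_path)


class TestFilterCollection:
    def setup_method(self):
        self.coll = [
            _set("a", "tf1", [], tissue="leaf", dna_state="methylated"),
            _set("b", "tf1", [], tissue="leaf", dna_state="unmethylated"),
            _set("c", "tf2", [], tissue="root", dna_state="methylated"),
        ]

    def test_matches_all_criteria(self):
        kept = filter_collection(self.coll, {"dna_state": "methylated", "tissue": "leaf"})
        assert [ps.set_id for ps in kept] == ["a"]

    def test_empty_criteria_is_identity(self):
        assert filter_collection(self.coll, {}) == self.coll

    def test_absent_key_matches_nothing(self):
        assert filter_collection(self.coll, {"assay": "dap-seq"}) == []


class TestMapTargets:
    def test_one_bp_overlap_is_enough(self):
        regions = [_region("g1", "chr1", 150, 1150)]
        tm = map_targets([_set("s", "tfA", [("chr1", 100, 200)])], regions)
        assert tm.pairs() == {("tfA", "g1")}

    def test_half_open_abutment_is_no_overlap(self):
        regions = [_region("g1", "chr1", 150, 1150)]
        tm = map_targets([_set("s", "tfA", [("chr1", 100, 150)])], regions)
        assert tm.pairs() == set()

    def test_disjoint_chromosome_naming_raises(self):
        regions = [_region("g1", "1", 0, 100)]
        with pytest.raises(ChromosomeMismatchError, match="chr1"):
            map_targets([_set("s", "tfA", [("chr1", 10, 20)])], regions)

    def test_duplicate_region_gene_ids_rejected(self):
        regions = [_region("g1", "chr1", 0, 100), _region("g1", "chr1", 200, 300)]
        with pytest.raises(DuplicateIdError):
            map_targets([], regions)

    def test_tf_level_union_across_peak_sets(self):
        """Splitting one peak set in two under the same TF changes nothing."""
        regions = [_region(f"g{i}", "chr1", i * 1000, i * 1000 + 500) for i in range(6)]
        peaks = [("chr1", i * 1000 + 100, i * 1000 + 200) for i in range(6)]
        merged = map_targets([_set("s", "tfA", peaks)], regions)
        split = map_targets(
            [_set("s1", "tfA", peaks[:3]), _set("s2", "tfA", peaks[3:])], regions)
        assert merged.pairs() == split.pairs()
        assert merged.entries == split.entries

    @pytest.mark.parametrize("trial_block", range(4))
    def test_matches_bruteforce_on_random_instances(self, trial_block):
        """map_targets equals the quadratic all-pairs scan, 250 trials/block."""
        rng = np.random.default_rng(1000 + trial_block)
        for _ in range(250):
            regions = []
            used = set()
            for i in range(int(rng.integers(1, 6))):
                s = int(rng.integers(0, 500))
                e = s + int(rng.integers(1, 120))
                regions.append(_region(f"g{i}", f"chr{rng.integers(1, 3)}", s, e))
            sets = []
            for t in range(int(rng.integers(1, 4))):
                peaks = []
                for _ in range(int(rng.integers(0, 10))):
                    s = int(rng.integers(0, 600))
                    peaks.append((f"chr{rng.integers(1, 3)}", s, s + int(rng.integers(1, 80))))
                sets.append(_set(f"s{t}", f"tf{t % 2}", peaks))
            expected = brute_overlap_pairs(sets, regions)
            region_chroms = {r.chrom for r in regions}
            peak_chroms = {p.chrom for ps in sets for p in ps.peaks}
            if peak_chroms and not (peak_chroms & region_chroms):
                continue  # naming-mismatch guard fires by design
            got = map_targets(sets, regions)
            assert got.pairs() == expected
            # supporting peaks really do overlap their region
            by_gene = {r.gene_id: r for r in regions}
            for (tf, gene), peaks in got.entries.items():
                r = by_gene[gene]
                for p in peaks:
                    assert p.chrom == r.chrom
                    assert min(p.end, r.end) - max(p.start, r.start) >= 1

    def test_monotone_under_added_peak_and_longer_regions(self):
        regions_short = [_region("g1", "chr1", 500, 1000)]
        regions_long = [_region("g1", "chr1", 0, 1000)]
        base = [_set("s", "tfA", [("chr1", 400, 450)])]
        assert map_targets(base, regions_short).pairs() == set()
        assert map_targets(base, regions_long).pairs() == {("tfA", "g1")}
        more = [_set("s", "tfA", [("chr1", 400, 450), ("chr1", 600, 650)])]
        assert map_targets(more, regions_short).pairs() >= map_targets(base, regions_short).pairs()
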