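"""Marker trimming/concatenation, PD, midpoint rooting, core-SNP matrices."""

import dendropy
import numpy as np
import pytest

from mgvkit.phylo import (MarkerAlignment, concatenate, core_snp_matrix,
                          filter_genomes, midpoint_root,
                          phylogenetic_diversity, total_branch_length,
                          trim_columns)
from mgvkit.synthgen import gen_toy_tree

from oracles import pd_path_union


def _tree(newick):
    return dendropy.Tree.get(data=newick, schema="newick")


class TestTrimColumns:
    def test_half_gapped_column_removed(self):
        aln = MarkerAlignment("m", {"a": "A-C", "b": "A-C",
                                    "c": "AAC", "d": "A-C"})
        # column 2 has 3/4 gaps; a 2/4 (=50%) column must also go
        half = MarkerAlignment("m", {"a": "A-", "b": "A-", "c": "AA", "d": "AA"})
        assert trim_columns(half).sequences == {"a": "A", "b": "A",
                                                "c": "A", "d": "A"}
        assert trim_columns(aln).sequences == {"a": "AC", "b": "AC",
                                               "c": "AC", "d": "AC"}

    def test_gap_free_unchanged(self):
        aln = MarkerAlignment("m", {"a": "ACDEF", "b": "ACDEF"})
        assert trim_columns(aln).sequences == aln.sequences

    def test_all_gap_column_removed(self):
        aln = MarkerAlignment("m", {"a": "A-F", "b": "C-G"})
        assert trim_columns(aln).sequences == {"a": "AF", "b": "CG"}

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            trim_columns(MarkerAlignment("m", {}))

    def test_ragged_rejected(self):
        with pytest.raises(ValueError):
            MarkerAlignment("m", {"a": "AC", "b": "A"})


class TestConcatenate:
    MARKERS = [
        MarkerAlignment("m1", {"g1": "A" * 10, "g2": "C" * 10}),
        MarkerAlignment("m2", {"g1": "D" * 20}),
        MarkerAlignment("m3", {"g1": "E" * 30, "g2": "F" * 30}),
    ]

    def test_missing_marker_gap_filled(self):
        rows, counts = concatenate(self.MARKERS, ["g1", "g2"])
        assert len(rows["g1"]) == len(rows["g2"]) == 60
        assert rows["g2"][10:30] == "-" * 20  # positions 11-30 are the fill
        assert counts == {"g1": 3, "g2": 2}

    def test_complete_genome_has_no_fill(self):
        rows, _ = concatenate(self.MARKERS, ["g1"])
        assert "-" not in rows["g1"]

    def test_empty_genome_set_rejected(self):
        with pytest.raises(ValueError):
            concatenate(self.MARKERS, [])


class TestFilterGenomes:
    def test_thresholds(self):
        rows = {
            "enough": "A" * 8 + "-" * 92,     # 3 markers, 8% columns
            "few_markers": "A" * 40 + "-" * 60,
            "sparse": "A" * 4 + "-" * 96,     # 5 markers, 4% columns
        }
        counts = {"enough": 3, "few_markers": 2, "sparse": 5}
        assert filter_genomes(rows, counts) == ["enough"]


class TestPhylogeneticDiversity:
    def test_full_subset_equals_total_length(self):
        tree = _tree(gen_toy_tree(12, seed=1))
        tips = [l.taxon.label for l in tree.leaf_node_iter()]
        assert phylogenetic_diversity(tree, tips) == pytest.approx(
            total_branch_length(tree))

    def test_sister_pair_on_balanced_quartet(self):
        tree = _tree("((a:1,b:1):1,(c:1,d:1):1);")
        assert phylogenetic_diversity(tree, ["a", "b"]) == pytest.approx(3.0)

    def test_empty_subset(self):
        tree = _tree("(a:1,b:2);")
        assert phylogenetic_diversity(tree, []) == 0.0

    def test_unknown_tip_rejected(self):
        tree = _tree("(a:1,b:2);")
        with pytest.raises(ValueError):
            phylogenetic_diversity(tree, ["zz"])

    def test_monotone_in_subset(self):
        tree = _tree(gen_toy_tree(10, seed=2))
        tips = sorted(l.taxon.label for l in tree.leaf_node_iter())
        values = [phylogenetic_diversity(tree, tips[:k])
                  for k in range(1, len(tips) + 1)]
        assert all(b >= a for a, b in zip(values, values[1:]))

    def test_equals_path_union_oracle(self):
        rng = np.random.default_rng(3)
        for seed in range(10):
            tree = _tree(gen_toy_tree(int(rng.integers(4, 20)), seed=seed))
            tips = [l.taxon.label for l in tree.leaf_node_iter()]
            subset = list(rng.choice(tips, size=max(1, len(tips) // 2),
                                     replace=False))
            assert phylogenetic_diversity(tree, subset) == pytest.approx(
                pd_path_union(tree, subset))


class TestMidpointRoot:
    def test_two_tips(self):
        rooted = midpoint_root(_tree("(a:2,b:4);"))
        depths = {l.taxon.label: l.distance_from_root()
                  for l in rooted.leaf_node_iter()}
        assert depths["a"] == pytest.approx(3.0)
        assert depths["b"] == pytest.approx(3.0)

    def test_idempotent(self):
        tree = _tree(gen_toy_tree(8, seed=4))
        once = midpoint_root(tree)
        twice = midpoint_root(once)
        d1 = sorted((l.taxon.label, round(l.distance_from_root(), 9))
                    for l in once.leaf_node_iter())
        d2 = sorted((l.taxon.label, round(l.distance_from_root(), 9))
                    for l in twice.leaf_node_iter())
        assert d1 == d2

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            midpoint_root(_tree("(a:0,b:0);"))


class TestCoreSNPMatrix:
    def test_position_coverage_boundary(self):
        aligned = {"ref": "ACGT", "g1": "AC-T", "g2": "TC--", "g3": "T---"}
        # position 1: 4/4 covered, alleles {A, T} -> kept
        # position 2: 3/4 covered (>=50%), invariant C -> dropped
        # position 3: 1/4 covered (<50%) -> dropped
        # position 4: 2/4 covered (=50%), alleles {T} invariant -> dropped
        matrix = core_snp_matrix(aligned)
        assert matrix.positions == [1]
        assert matrix.data.loc["g2", 1] == "T"

    def test_genome_data_rule(self):
        aligned = {
            "ref": "ACGTACGTAC",
            "g1":  "TCGTACGTAC",
            "g2":  "AGGTACGTAC",
            "g3":  "AC--------",  # data at 2 of 3 retained? -> compute
        }
        matrix = core_snp_matrix(aligned)
        # variant positions: 1 (A/T/A/A), 2 (C/C/G/C); g3 covers both
        assert matrix.positions == [1, 2]
        assert set(matrix.genomes) == {"ref", "g1", "g2", "g3"}

    def test_sparse_genome_dropped(self):
        aligned = {
            "ref": "ACGTA",
            "g1":  "TCGTC",
            "g2":  "TGTAC",
            "g3":  "A----",  # data at 1/5 positions
        }
        matrix = core_snp_matrix(aligned)
        retained = len(matrix.positions)
        assert retained >= 2
        assert "g3" not in matrix.genomes

    def test_identical_genomes_no_variants(self):
        matrix = core_snp_matrix({"ref": "ACGT", "g1": "ACGT"})
        assert matrix.positions == []

    def test_fewer_than_two_rejected(self):
        with pytest.raises(ValueError):
            core_snp_matrix({"ref": "ACGT"})
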