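"""Viral signature computation, rule evaluation and the benchmark harness."""

import pytest
from hypothesis import given, settings, strategies as st

from mgvkit.classify import (ClassificationMetrics, ContigFeatures,
                             RuleClause, RuleSet, classify_protein_hits,
                             clause_grid, compute_metrics, contig_features,
                             evaluate, grid_search, strand_switch_rate)
from mgvkit.synthgen import BenchmarkSpec, gen_mock_benchmark

from oracles import brute_force_grid_maximum


def features(contig_id="c", n_genes=10, n_viral=0, n_microbial=0,
             nt_score=0.5, rate=0.0, length=10_000):
    return ContigFeatures(contig_id=contig_id, n_genes=n_genes,
                          n_viral_hits=n_viral, n_microbial_hits=n_microbial,
                          nt_score=nt_score, strand_switch_rate=rate,
                          length=length)


class TestStrandSwitchRate:
    @pytest.mark.parametrize("strands, expected", [
        ("++++", 0.0),
        ("+-+-", 0.75),   # 3 switches over 4 genes
        ("+", 0.0),
        ("++--", 0.25),
    ])
    def test_rates(self, strands, expected, make_gene):
        genes = [make_gene(gene_index=i + 1, start=1 + 400 * i,
                           end=300 + 400 * i, strand=s)
                 for i, s in enumerate(strands)]
        assert strand_switch_rate(genes) == expected

    def test_empty(self):
        assert strand_switch_rate([]) == 0.0

    def test_unsorted_rejected(self, make_gene):
        genes = [make_gene(start=500, end=800), make_gene(start=1, end=300)]
        with pytest.raises(ValueError, match="sorted"):
            strand_switch_rate(genes)


class TestProteinHitClassification:
    def test_top_hit_database_wins(self, make_hit):
        assert classify_protein_hits([make_hit(bit_score=120.0)],
                                     [make_hit(bit_score=80.0)]) == "viral"
        assert classify_protein_hits([], [make_hit()]) == "microbial"
        assert classify_protein_hits([], []) == "none"

    def test_tie_resolves_viral(self, make_hit):
        assert classify_protein_hits([make_hit(bit_score=100.0)],
                                     [make_hit(bit_score=100.0)]) == "viral"


class TestContigFeatures:
    def test_aggregation(self, make_gene):
        genes = [make_gene(gene_index=i + 1, start=1 + 400 * i,
                           end=300 + 400 * i) for i in range(10)]
        labels = {i + 1: "viral" for i in range(6)}
        labels[7] = "microbial"
        labels[8] = labels[9] = labels[10] = "none"
        f = contig_features("c", 12_000, genes, labels, 0.8)
        assert (f.n_viral_hits, f.n_microbial_hits, f.n_genes) == (6, 1, 10)
        assert f.strand_switch_rate == 0.0

    def test_no_genes(self):
        f = contig_features("c", 2_000, [], {}, 0.2)
        assert (f.n_genes, f.strand_switch_rate) == (0, 0.0)

    def test_bad_nt_score(self):
        with pytest.raises(ValueError, match="nt_score"):
            contig_features("c", 2_000, [], {}, 1.2)

    def test_label_count_invariant(self):
        with pytest.raises(ValueError):
            features(n_genes=3, n_viral=2, n_microbial=2)


class TestRuleEvaluation:
    def test_clause_needs_a_threshold(self):
        with pytest.raises(ValueError):
            RuleClause()

    def test_at_most_five_clauses(self):
        clauses = [RuleClause(min_viral_hits=i) for i in range(6)]
        with pytest.raises(ValueError, match="5"):
            RuleSet({1000: clauses})

    def test_disjunction(self):
        rs = RuleSet({1000: [RuleClause(min_viral_hits=50),
                             RuleClause(min_nt_score=0.7)]})
        assert evaluate(features(nt_score=0.8, length=1500), rs)
        assert not evaluate(features(nt_score=0.5, length=1500), rs)

    def test_boundaries_inclusive(self):
        rs = RuleSet({10_000: [RuleClause(min_viral_hits=3,
                                          max_strand_switch_rate=0.2)]})
        assert evaluate(features(n_viral=3, rate=0.2), rs)
        assert not evaluate(features(n_viral=2, rate=0.2), rs)
        assert not evaluate(features(n_viral=3, rate=0.21), rs)

    def test_length_class_is_largest_at_or_below(self):
        rs = RuleSet({1000: [RuleClause(min_viral_hits=1)]})
        assert rs.length_class(1_500) == 1000
        assert rs.length_class(100_000) == 100_000
        assert rs.length_class(99_999) == 50_000
        with pytest.raises(ValueError):
            rs.length_class(999)

    @given(extra_viral=st.integers(0, 5), fewer_microbial=st.integers(0, 3),
           n_viral=st.integers(0, 10), n_microbial=st.integers(0, 3),
           min_v=st.integers(0, 8), max_m=st.integers(0, 3))
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_evaluate_monotone(self, extra_viral, fewer_microbial, n_viral,
                               n_microbial, min_v, max_m):
        """More viral evidence never flips a viral call to non-viral."""
        rs = RuleSet({1000: [RuleClause(min_viral_hits=min_v,
                                        max_microbial_hits=max_m)]})
        base = features(n_genes=30, n_viral=n_viral, n_microbial=n_microbial,
                        length=1500)
        better = features(n_genes=30, n_viral=n_viral + extra_viral,
                          n_microbial=max(0, n_microbial - fewer_microbial),
                          length=1500)
        if evaluate(base, rs):
            assert evaluate(better, rs)


class TestMetrics:
    def test_perfect(self):
        truth = {"v": True, "h": False}
        m = compute_metrics({"v": True, "h": False}, truth)
        assert (m.tpr, m.fpr, m.score) == (100.0, 0.0, 100.0)

    def test_published_score_arithmetic(self):
        # TPR 74% at FPR 0.38% corresponds to a classification score of 55.0
        m = ClassificationMetrics(tpr=74.0, fpr=0.38, score=74.0 - 50 * 0.38)
        assert m.score == pytest.approx(55.0)

    def test_all_negative_predictions(self):
        truth = {"v": True, "h": False}
        m = compute_metrics({"v": False, "h": False}, truth)
        assert (m.tpr, m.fpr, m.score) == (0.0, 0.0, 0.0)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            compute_metrics({"a": True}, {"a": True})

    def test_relabelling_invariance(self):
        truth = {"a": True, "b": True, "c": False, "d": False}
        preds = {"a": True, "b": False, "c": True, "d": False}
        m1 = compute_metrics(preds, truth)
        relabel = {"a": "w", "b": "x", "c": "y", "d": "z"}
        m2 = compute_metrics({relabel[k]: v for k, v in preds.items()},
                             {relabel[k]: v for k, v in truth.items()})
        assert (m1.tpr, m1.fpr) == (m2.tpr, m2.fpr)


GRIDS = {
    "min_viral_hits": [None, 1, 3, 5],
    "max_microbial_hits": [None, 0, 1],
    "min_nt_score": [None, 0.5, 0.8],
    "max_strand_switch_rate": [None, 0.2],
}


class TestGridSearch:
    def test_single_combination_returned(self):
        bench = gen_mock_benchmark(BenchmarkSpec(seed=3, n_per_category=20,
                                                 lengths=(1000,)))
        result = grid_search(bench.features, bench.truth,
                             {"min_viral_hits": [2]}, lengths=(1000,))
        assert len(result[1000]) == 1
        assert result[1000][0].clause == RuleClause(min_viral_hits=2)

    def test_matches_brute_force_oracle(self):
        bench = gen_mock_benchmark(BenchmarkSpec(seed=5, n_per_category=40,
                                                 lengths=(5000,)))
        result = grid_search(bench.features, bench.truth, GRIDS,
                             lengths=(5000,))
        clauses = clause_grid(GRIDS["min_viral_hits"],
                              GRIDS["max_microbial_hits"],
                              GRIDS["min_nt_score"],
                              GRIDS["max_strand_switch_rate"])
        oracle_best = brute_force_grid_maximum(bench.features, bench.truth,
                                               clauses)
        assert result[5000][0].metrics.score == pytest.approx(oracle_best)

    def test_deterministic_ordering(self):
        bench = gen_mock_benchmark(BenchmarkSpec(seed=7, n_per_category=30,
                                                 lengths=(2000,)))
        r1 = grid_search(bench.features, bench.truth, GRIDS, lengths=(2000,))
        r2 = grid_search(bench.features, bench.truth, GRIDS, lengths=(2000,))
        assert [rc.clause for rc in r1[2000]] == [rc.clause for rc in r2[2000]]
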