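"""Domain types and the plain-text readers/writers."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mgvkit.core import (ContigRecord, GeneCall, SearchHit, TaxonomyLabel,
                         HOST_RANKS, gc_content, reverse_complement)
from mgvkit.io import (read_fasta, read_gene_table, read_hit_table,
                       write_fasta, write_gene_table, write_hit_table)
from mgvkit.votu import merge_intervals


class TestContigRecord:
    def test_gc_ignores_n(self):
        assert ContigRecord("c", "GCGCNNNN").gc == 1.0
        assert gc_content("ATAT") == 0.0
        assert gc_content("NNNN") == 0.0

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            ContigRecord("c", "")

    def test_subsequence_inclusive_coordinates(self):
        rec = ContigRecord("c", "ACGTACGT")
        sub = rec.subsequence(2, 5, "|part")
        assert sub.sequence == "CGTA"
        assert sub.id == "c|part"
        with pytest.raises(ValueError):
            rec.subsequence(0, 5, "|bad")
        with pytest.raises(ValueError):
            rec.subsequence(2, 9, "|bad")

    def test_reverse_complement(self):
        assert reverse_complement("ACGTN") == "NACGT"
        assert reverse_complement(reverse_complement("GATTACA")) == "GATTACA"


class TestGeneCall:
    def test_invalid_strand(self):
        with pytest.raises(ValueError, match="strand"):
            GeneCall("c", 1, 1, 30, ".")

    def test_length_is_inclusive(self, make_gene):
        assert make_gene(start=11, end=40).length == 30

    @given(start=st.integers(1, 10_000), span=st.integers(0, 10_000))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_interval_length_property(self, start, span):
        gene = GeneCall("c", 1, start, start + span, "+")
        assert gene.length == span + 1


class TestSearchHit:
    def test_reversed_subject_normalised(self):
        hit = SearchHit.normalised("q", "t", 95.0, 100, 5, 0, 1, 100,
                                   500, 401, 1e-10, 90.0)
        assert (hit.sstart, hit.send, hit.subject_reversed) == (401, 500, True)

    def test_unnormalised_rejected(self):
        with pytest.raises(ValueError):
            SearchHit("q", "t", 95.0, 100, 5, 0, 1, 100, 500, 401, 1e-10, 90.0)


class TestTaxonomyLabel:
    def test_lowest_rank_and_truncation(self):
        label = TaxonomyLabel({"baltimore": "dsDNA", "order": "O",
                               "family": "F", "genus": "G"})
        assert label.lowest_rank() == "genus"
        assert label.truncated("family").as_dict() == {
            "baltimore": "dsDNA", "order": "O", "family": "F"}

    def test_unknown_rank_rejected(self):
        with pytest.raises(ValueError):
            TaxonomyLabel({"species": "S"})  # species is host-side only
        assert TaxonomyLabel({"species": "S"}, ladder=HOST_RANKS).get("species") == "S"


class TestFasta:
    def test_round_trip_random_records(self, tmp_path):
        rng = np.random.default_rng(11)
        records = [
            ContigRecord(f"r{i}", "".join(rng.choice(list("ACGT"),
                                                     size=rng.integers(1, 500))))
            for i in range(100)
        ]
        path = tmp_path / "r.fna"
        write_fasta(records, path)
        back = read_fasta(path)
        assert [r.id for r in back] == [r.id for r in records]
        assert [r.sequence for r in back] == [r.sequence for r in records]

    def test_file_order_preserved(self, tmp_path):
        path = tmp_path / "two.fna"
        path.write_text(">b\nACGT\n>a\nTTTT\n")
        assert [r.id for r in read_fasta(path)] == ["b", "a"]

    def test_duplicate_id_reported(self, tmp_path):
        path = tmp_path / "dup.fna"
        path.write_text(">dup1\nACGT\n>dup1\nACGT\n")
        with pytest.raises(ValueError, match="dup1"):
            read_fasta(path)


class TestGeneTable:
    def test_sorted_and_indexed(self, tmp_path):
        path = tmp_path / "genes.tsv"
        rows = [
            "c1\tcaller\tCDS\t500\t799\t12.5\t+\t0\tgenetic_code=11",
            "c1\tcaller\tCDS\t10\t309\t8.0\t-\t0\tgenetic_code=11",
            "c1\tcaller\tCDS\t900\t1199\t3.0\t+\t0\tgenetic_code=11",
        ]
        path.write_text("\n".join(rows) + "\n")
        genes = read_gene_table(path)
        assert [g.start for g in genes] == [10, 500, 900]
        assert [g.gene_index for g in genes] == [1, 2, 3]
        assert genes[0].strand == "-"
        assert genes[0].coding_score == 8.0

    def test_bad_strand_rejected(self, tmp_path):
        path = tmp_path / "genes.tsv"
        path.write_text("c1\tx\tCDS\t1\t30\t1.0\t.\t0\tgenetic_code=11\n")
        with pytest.raises(ValueError, match="strand"):
            read_gene_table(path)

    def test_start_after_end_rejected(self, tmp_path):
        path = tmp_path / "genes.tsv"
        path.write_text("c1\tx\tCDS\t50\t30\t1.0\t+\t0\tgenetic_code=11\n")
        with pytest.raises(ValueError, match="start > end"):
            read_gene_table(path)

    def test_empty_file(self, tmp_path):
        path = tmp_path / "empty.tsv"
        path.write_text("")
        assert read_gene_table(path) == []

    def test_round_trip(self, tmp_path, make_gene):
        genes = [make_gene(gene_index=1, start=1, end=300, protein="MKV"),
                 make_gene(gene_index=2, start=400, end=900, strand="-")]
        path = tmp_path / "genes.tsv"
        write_gene_table(genes, path)
        assert read_gene_table(path) == genes


class TestHitTable:
    ROW = "q1\tt1\t97.500\t900\t22\t1\t1\t900\t100\t999\t1e-10\t1234\n"

    def test_parse(self, tmp_path):
        path = tmp_path / "hits.tsv"
        path.write_text(self.ROW)
        (hit,) = read_hit_table(path)
        assert hit.percent_identity == 97.5
        assert hit.e_value == 1e-10
        assert hit.bit_score == 1234.0

    def test_wrong_column_count_reports_line(self, tmp_path):
        path = tmp_path / "hits.tsv"
        path.write_text("q1\tt1\t97.5\t900\t22\t1\t1\t900\t100\t999\t1e-10\n")
        with pytest.raises(ValueError, match=":1"):
            read_hit_table(path)

    def test_round_trip_with_reversed_subject(self, tmp_path):
        path = tmp_path / "hits.tsv"
        path.write_text("q1\tt1\t97.5\t900\t22\t1\t1\t900\t999\t100\t1e-10\t1234\n")
        hits = read_hit_table(path)
        assert hits[0].subject_reversed
        out = tmp_path / "out.tsv"
        write_hit_table(hits, out)
        assert read_hit_table(out) == hits


@given(st.lists(st.tuples(st.integers(1, 200), st.integers(0, 50)),
                min_size=0, max_size=20))
@settings(max_examples=100, deadline=None, derandomize=True)
def test_merge_intervals_matches_set_union(pairs):
    """Interval-union arithmetic agrees with an explicit base-set oracle."""
    intervals = [(s, s + w) for s, w in pairs]
    expected = len({b for s, e in intervals for b in range(s, e + 1)})
    assert merge_intervals(intervals) == expected
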