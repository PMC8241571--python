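import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the shared oracles module

from mgvkit.core import GeneCall, SearchHit


@pytest.fixture
def make_gene():
    """Factory for GeneCalls with sensible defaults."""
    def _make(contig_id="c", gene_index=1, start=1, end=300, strand="+",
              **kwargs):
        return GeneCall(contig_id=contig_id, gene_index=gene_index,
                        start=start, end=end, strand=strand, **kwargs)
    return _make


@pytest.fixture
def make_hit():
    """Factory for SearchHits with sensible defaults."""
    def _make(query_id="q", target_id="t", percent_identity=90.0,
              alignment_length=100, mismatches=0, gap_opens=0, qstart=1,
              qend=100, sstart=1, send=100, e_value=1e-20, bit_score=100.0):
        return SearchHit(query_id, target_id, percent_identity,
                         alignment_length, mismatches, gap_opens, qstart,
                         qend, sstart, send, e_value, bit_score)
    return _make
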