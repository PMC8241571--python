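"""Detection of viruses using alternative genetic codes.

Some gut phages (notably crAss-like phages) reassign a stop codon to an
amino acid. Such genomes look gene-poor under the standard code because
translation appears to terminate early at every recoded stop. Detection
re-calls genes under candidate codes and compares the summed per-gene
coding-potential score per contig: an alternative code is called when its
total is the greatest and at least 10% greater than the standard code's.

Candidate codes: 11 (standard), 4 (TGA recoded; translation-table codes 4
and 25 both reassign TGA and are represented by the single label 4),
15 (TAG recoded) and 90 (TAA recoded). To limit false positives the
procedure is restricted to contigs longer than 10 kb with GC content below
50% — stop codons are AT-rich, so low-GC genomes are where spurious
in-frame stops are informative.

The production gene caller is pluggable (any caller emitting per-gene
coding scores under a specified code); a naive open-reading-frame scorer
ships for testing, scoring each ORF by its length in codons.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

from .core import ContigRecord, GeneCall, reverse_complement

logger = logging.getLogger(__name__)

MIN_LENGTH = 10_000
MAX_GC = 0.50
MARGIN = 1.10

#: Stop codons under each candidate code.
STOP_CODONS: dict[int, frozenset[str]] = {
    11: frozenset({"TAA", "TAG", "TGA"}),
    4: frozenset({"TAA", "TAG"}),   # TGA recoded
    15: frozenset({"TAA", "TGA"}),  # TAG recoded
    90: frozenset({"TAG", "TGA"}),  # TAA recoded
}

CANDIDATE_CODES = (11, 4, 15, 90)


@dataclass(frozen=True)
class CodeScore:
    contig_id: str
    code: int
    total_coding_score: float


def eligible(contig: ContigRecord, min_length: int = MIN_LENGTH,
             max_gc: float = MAX_GC) -> bool:
    """Screening rule: only contigs > 10 kb with GC < 50% are evaluated."""
    return contig.length > min_length and contig.gc < max_gc


def sum_coding_scores(genes: Sequence[GeneCall]) -> float:
    """Total coding potential of one contig under one genetic code."""
    return float(sum(g.coding_score for g in genes))


def detect_code(scores: Mapping[int, float], margin: float = MARGIN) -> int:
    """Call the genetic code of a contig from per-code total coding scores.

    Returns the alternative code whose total is both the global maximum and
    at least ``margin`` (default 1.10, i.e. 10% greater) times the standard
    code's total; otherwise the standard code 11. The margin is always
    measured against code 11, not the runner-up.
    """
    if 11 not in scores:
        raise ValueError("standard-code (11) score is required")
    standard = scores[11]
    best_code, best_score = 11, standard
    for code in sorted(scores):
        if code == 11:
            continue
        if scores[code] > best_score:
            best_code, best_score = code, scores[code]
    if best_code == 11 or best_score <= 0:
        return 11
    if standard <= 0:
        return best_code
    # ratio comparison keeps the margin scale-invariant and float-robust at
    # the exact 10% boundary
    if best_score / standard + 1e-12 >= margin:
        return best_code
    return 11


# ---------------------------------------------------------------------------
# naive ORF-based gene caller (test stand-in for an external caller)

GeneCaller = Callable[[ContigRecord, int], Sequence[GeneCall]]


def call_genes_naive(contig: ContigRecord, code: int = 11,
                     min_orf_codons: int = 30) -> list[GeneCall]:
    """Six-frame ORF finder whose coding score is ORF length in codons.

    An ORF is a maximal run of non-stop codons under ``code``; no start
    codon is required. Deliberately simple: it exists so code comparison is
    testable without an external gene caller, not as a production caller.
    """
    stops = STOP_CODONS[code]
    seq = contig.sequence.upper()
    n = len(seq)
    genes: list[tuple[int, int, str, float]] = []

    for strand, s in (("+", seq), ("-", reverse_complement(seq))):
        for frame in range(3):
            orf_start = frame
            pos = frame
            while pos + 3 <= n:
                codon = s[pos : pos + 3]
                if codon in stops:
                    _emit(genes, orf_start, pos, strand, n, min_orf_codons)
                    orf_start = pos + 3
                pos += 3
            _emit(genes, orf_start, pos, strand, n, min_orf_codons)

    genes.sort(key=lambda g: (g[0], g[1]))
    return [
        GeneCall(contig_id=contig.id, gene_index=i, start=start, end=end,
                 strand=strand, coding_score=score, genetic_code=code)
        for i, (start, end, strand, score) in enumerate(genes, start=1)
    ]


def _emit(genes: list, orf_start: int, orf_end: int, strand: str,
          seq_len: int, min_orf_codons: int) -> None:
    """Record an ORF spanning [orf_start, orf_end) on the scanned strand."""
    codons = (orf_end - orf_start) // 3
    if codons < min_orf_codons:
        return
    if strand == "+":
        start, end = orf_start + 1, orf_start + codons * 3
    else:  # map back to forward-strand coordinates
        end = seq_len - orf_start
        start = end - codons * 3 + 1
    genes.append((start, end, strand, float(codons)))


def score_codes(contig: ContigRecord,
                caller: GeneCaller = call_genes_naive,
                codes: Sequence[int] = CANDIDATE_CODES) -> dict[int, float]:
    """Per-code total coding scores for one contig."""
    return {code: sum_coding_scores(caller(contig, code)) for code in codes}


def detect_contig_code(contig: ContigRecord,
                       caller: GeneCaller = call_genes_naive,
                       margin: float = MARGIN) -> int:
    """End-to-end call for one contig: eligibility screen, per-code gene
    calling, and the margin comparison."""
    if not eligible(contig):
        return 11
    return detect_code(score_codes(contig, caller), margin=margin)
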