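"""Viral genome quality control.

Covers the evidence this package computes itself — terminal repeats, large
intragenomic repeats, provirus flank trimming — plus tier assignment and the
rRNA contamination screen applied to externally supplied completeness
estimates and rRNA search hits. Completeness estimation itself (reference
comparison) is an external step whose output is consumed.

Quality tiers partition genomes as: complete (closure evidence — DTR, ITR or
provirus boundaries — plus >90% completeness), high (>90%), medium (50-90%,
inclusive both ends), low (<50%), undetermined (no completeness estimate).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

from .core import ContigRecord, SearchHit, reverse_complement
from .votu import merge_intervals

logger = logging.getLogger(__name__)

MIN_TERMINAL_REPEAT = 20
MAX_TERMINAL_REPEAT_SEARCH = 5000
LARGE_REPEAT_SEED = 100
LARGE_REPEAT_MAX_SPAN = 0.30

TIERS = ("complete", "high", "medium", "low", "undetermined")
COMPLETE_EVIDENCE = ("DTR", "ITR", "provirus_boundaries", "none")


@dataclass(frozen=True)
class TerminalRepeat:
    kind: str  # "DTR" or "ITR"
    repeat_length: int
    repeat_sequence: str


@dataclass(frozen=True)
class QualityRecord:
    contig_id: str
    completeness: Optional[float]  # percent, None = undetermined
    complete_evidence: str         # one of COMPLETE_EVIDENCE
    tier: str
    provirus: bool = False
    large_repeat: bool = False


def _clean_match(a: str, b: str) -> bool:
    """Exact match in which N never matches (not even another N)."""
    return a == b and "N" not in a and "n" not in a


def detect_terminal_repeats(sequence: str,
                            min_len: int = MIN_TERMINAL_REPEAT,
                            max_len: Optional[int] = None) -> Optional[TerminalRepeat]:
    """Longest exact terminal repeat, scanning length downward.

    A direct terminal repeat (DTR) is a prefix equal to a suffix; an inverted
    terminal repeat (ITR) is a prefix equal to the reverse complement of the
    suffix. Repeat lengths from min(len // 2, 5000) down to ``min_len`` are
    tried; DTR is reported in preference to ITR when both exist.
    """
    n = len(sequence)
    if n <= 2 * min_len:
        return None
    upper = min(n // 2, MAX_TERMINAL_REPEAT_SEARCH if max_len is None else max_len)

    dtr = itr = None
    for k in range(upper, min_len - 1, -1):
        prefix = sequence[:k]
        suffix = sequence[-k:]
        if dtr is None and _clean_match(prefix, suffix):
            dtr = TerminalRepeat("DTR", k, prefix)
            break  # DTR preferred; no longer ITR can change the outcome
        if itr is None and _clean_match(prefix, reverse_complement(suffix)):
            itr = TerminalRepeat("ITR", k, prefix)
    return dtr if dtr is not None else itr


def large_repeat_flag(sequence: str,
                      seed_len: int = LARGE_REPEAT_SEED,
                      max_span: float = LARGE_REPEAT_MAX_SPAN) -> bool:
    """True iff repeated sequence spans strictly more than ``max_span`` of
    the contig.

    Repeats are detected by exact self-comparison: every ``seed_len``-mer
    occurring more than once marks its occurrence interval, and the flag
    compares the size of the interval union against the contig length.
    """
    n = len(sequence)
    if n < 2 * seed_len:
        return False
    positions: dict[str, list[int]] = {}
    for i in range(n - seed_len + 1):
        kmer = sequence[i : i + seed_len]
        positions.setdefault(kmer, []).append(i)
    intervals = []
    for kmer, occs in positions.items():
        if len(occs) > 1 and "N" not in kmer:
            intervals.extend((i + 1, i + seed_len) for i in occs)
    if not intervals:
        return False
    span = merge_intervals(intervals)
    return span > max_span * n


def trim_provirus(contig: ContigRecord, viral_start: int,
                  viral_end: int) -> ContigRecord:
    """Remove flanking host sequence around an integrated provirus.

    Returns the inclusive subsequence [viral_start, viral_end] as a new
    record with a deterministic id suffix (no suffix when the full range is
    requested, which makes full-range trimming idempotent).
    """
    if viral_start == 1 and viral_end == contig.length:
        return contig
    suffix = f"|provirus_{viral_start}_{viral_end}"
    return contig.subsequence(viral_start, viral_end, suffix)


def assign_quality_tier(completeness: Optional[float],
                        complete_evidence: str = "none") -> str:
    """Map a completeness estimate and closure evidence to a quality tier."""
    if complete_evidence not in COMPLETE_EVIDENCE:
        raise ValueError(f"unknown completeness evidence {complete_evidence!r}")
    if completeness is None:
        return "undetermined"
    if not (0.0 <= completeness <= 100.0):
        raise ValueError(f"completeness {completeness} outside [0, 100]")
    if completeness > 90.0:
        return "complete" if complete_evidence != "none" else "high"
    if completeness >= 50.0:
        return "medium"
    return "low"


def rrna_contamination(hits: Sequence[SearchHit],
                       model_lengths: Mapping[str, int],
                       min_coverage: float = 0.70,
                       max_evalue: float = 1e-5) -> bool:
    """rRNA screen: contaminated iff some hit covers >= 70% of its 16S/18S
    model with e-value < 1e-5. Hit subject coordinates are on the model."""
    for hit in hits:
        if hit.target_id not in model_lengths:
            raise ValueError(f"no model length for rRNA model {hit.target_id!r}")
        coverage = (hit.send - hit.sstart + 1) / model_lengths[hit.target_id]
        if coverage >= min_coverage and hit.e_value < max_evalue:
            return True
    return False


def quality_record(contig: ContigRecord,
                   completeness: Optional[float],
                   provirus: bool = False,
                   provirus_boundaries: bool = False) -> QualityRecord:
    """Full per-contig QC: repeat evidence, tier and large-repeat flag."""
    repeat = detect_terminal_repeats(contig.sequence)
    if repeat is not None:
        evidence = repeat.kind
    elif provirus_boundaries:
        evidence = "provirus_boundaries"
    else:
        evidence = "none"
    tier = assign_quality_tier(completeness, evidence)
    return QualityRecord(contig_id=contig.id, completeness=completeness,
                         complete_evidence=evidence, tier=tier,
                         provirus=provirus,
                         large_repeat=large_repeat_flag(contig.sequence))
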