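"""Species-level clustering of viral genomes (vOTUs).

Two genomes belong to the same viral operational taxonomic unit when they
share >= 95% average nucleotide identity (ANI) over >= 85% alignment fraction
(AF) of the shorter sequence. ANI is the length-weighted mean identity across
local alignments; AF is the fraction of the shorter genome covered by the
union of alignment intervals. Clustering is greedy and centroid-based:
genomes are sorted by length, the longest unassigned genome seeds a cluster,
and every genome within the ANI/AF thresholds of that centroid joins it.

Alignments normally come from an external all-vs-all nucleotide search
(hit tables are accepted verbatim); a built-in seeded aligner covers the
small-genome path so the ANI/AF arithmetic and clustering are testable with
no external binary. The built-in aligner finds exact k-mer seeds, groups
them by diagonal, and extracts maximal ungapped high-scoring segments along
each diagonal (match +1 / mismatch -1, X-drop termination) — adequate for
the substitution-dominated divergence regime the species threshold operates
in, not a replacement for a gapped search engine.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Optional, Sequence

import numpy as np

from .core import ContigRecord, SearchHit, reverse_complement

logger = logging.getLogger(__name__)

MIN_ANI = 95.0
MIN_AF = 85.0
BLAST_MIN_IDENTITY = 90.0  # local alignments below this identity are discarded

ALIGNER_KMER = 15
ALIGNER_MIN_SCORE = 25
ALIGNER_XDROP = 20
ALIGNER_MAX_LENGTH = 100_000


@dataclass(frozen=True)
class PairwiseANI:
    query_id: str
    target_id: str
    ani: float        # percent
    af_shorter: float # percent of the shorter genome covered
    n_alignments: int


@dataclass(frozen=True)
class VOTU:
    representative_id: str
    member_ids: frozenset[str]


def merge_intervals(intervals: Sequence[tuple[int, int]]) -> int:
    """Total bases covered by the union of 1-based inclusive intervals."""
    if not intervals:
        return 0
    covered = 0
    cur_start = cur_end = None
    for start, end in sorted(intervals):
        if start > end:
            raise ValueError(f"invalid interval ({start}, {end})")
        if cur_end is None:
            cur_start, cur_end = start, end
        elif start <= cur_end + 1:
            cur_end = max(cur_end, end)
        else:
            covered += cur_end - cur_start + 1
            cur_start, cur_end = start, end
    covered += cur_end - cur_start + 1
    return covered


def pairwise_ani(alignments: Sequence[SearchHit], len_q: int, len_t: int,
                 min_identity: float = BLAST_MIN_IDENTITY) -> Optional[PairwiseANI]:
    """Length-weighted ANI and shorter-genome AF from local alignments.

    Alignments below ``min_identity`` percent identity are discarded first
    (mirroring the identity floor applied in the external search). Returns
    None when no alignment survives: such a pair has no edge.
    """
    hits = [h for h in alignments if h.percent_identity >= min_identity]
    if not hits:
        return None
    total_len = sum(h.alignment_length for h in hits)
    ani = sum(h.percent_identity * h.alignment_length for h in hits) / total_len
    if len_q <= len_t:
        intervals = [(h.qstart, h.qend) for h in hits]
        shorter = len_q
    else:
        intervals = [(h.sstart, h.send) for h in hits]
        shorter = len_t
    af = min(100.0, 100.0 * merge_intervals(intervals) / shorter)
    return PairwiseANI(query_id=hits[0].query_id, target_id=hits[0].target_id,
                       ani=ani, af_shorter=af, n_alignments=len(hits))


# ---------------------------------------------------------------------------
# built-in small-scale local aligner

def _seed_diagonals(a: np.ndarray, b: np.ndarray, k: int) -> list[int]:
    """Diagonals (i - j) carrying at least one exact k-mer match."""
    index: dict[bytes, list[int]] = {}
    bb = b.tobytes()
    for j in range(0, len(b) - k + 1):
        index.setdefault(bb[j : j + k], []).append(j)
    ab = a.tobytes()
    diagonals: set[int] = set()
    for i in range(0, len(a) - k + 1):
        for j in index.get(ab[i : i + k], ()):
            diagonals.add(i - j)
    return sorted(diagonals)


def _diagonal_segments(match: np.ndarray, min_score: int,
                       xdrop: int) -> list[tuple[int, int, int]]:
    """Maximal ungapped segments (start, end, score) along one diagonal.

    Linear scan with +1/-1 scoring: the running score resets below zero
    (Kadane) and a segment is emitted when the score drops ``xdrop`` below
    its running maximum or the diagonal ends.
    """
    segments = []
    score = best = 0
    seg_start = 0
    best_end = -1
    for idx, m in enumerate(match):
        score += 1 if m else -1
        if score > best:
            best, best_end = score, idx
        if score < 0 or score <= best - xdrop:
            if best >= min_score:
                segments.append((seg_start, best_end, best))
            score = best = 0
            seg_start = idx + 1
            best_end = -1
    if best >= min_score:
        segments.append((seg_start, best_end, best))
    return segments


def _align_one_strand(a: np.ndarray, b: np.ndarray, query_id: str,
                      target_id: str, reverse: bool, k: int,
                      min_score: int, xdrop: int) -> list[SearchHit]:
    hits = []
    lb = len(b)
    for d in _seed_diagonals(a, b, k):
        i0 = max(0, d)
        i1 = min(len(a), lb + d)
        if i1 - i0 < min_score:
            continue
        match = a[i0:i1] == b[i0 - d : i1 - d]
        for s, e, score in _diagonal_segments(match, min_score, xdrop):
            length = e - s + 1
            n_match = int(match[s : e + 1].sum())
            qstart, qend = i0 + s + 1, i0 + e + 1
            jstart, jend = i0 + s - d, i0 + e - d  # 0-based on this strand of b
            if reverse:
                sstart, send = lb - jend, lb - jstart  # back to forward coords
            else:
                sstart, send = jstart + 1, jend + 1
            hits.append(SearchHit(
                query_id=query_id, target_id=target_id,
                percent_identity=100.0 * n_match / length,
                alignment_length=length, mismatches=length - n_match,
                gap_opens=0, qstart=qstart, qend=qend,
                sstart=sstart, send=send, e_value=0.0,
                bit_score=float(score), subject_reversed=reverse))
    return hits


def _dedupe_hits(hits: list[SearchHit]) -> list[SearchHit]:
    """Drop query-interval duplicates, keeping the highest-scoring hit."""
    hits = sorted(hits, key=lambda h: (-h.bit_score, h.qstart, h.qend))
    kept: list[SearchHit] = []
    for h in hits:
        if any(h.qstart >= k.qstart and h.qend <= k.qend for k in kept):
            continue
        kept.append(h)
    return sorted(kept, key=lambda h: (h.qstart, h.qend))


def align_pair(seq_a: str, seq_b: str, query_id: str = "a",
               target_id: str = "b", k: int = ALIGNER_KMER,
               min_score: int = ALIGNER_MIN_SCORE,
               xdrop: int = ALIGNER_XDROP,
               max_length: int = ALIGNER_MAX_LENGTH) -> list[SearchHit]:
    """Local ungapped alignments between two sequences, both strands."""
    if len(seq_a) > max_length or len(seq_b) > max_length:
        raise ValueError(
            f"built-in aligner limited to sequences <= {max_length} bp; "
            "use an external search for larger genomes"
        )
    a = np.frombuffer(seq_a.upper().encode(), dtype="S1")
    b_fwd = np.frombuffer(seq_b.upper().encode(), dtype="S1")
    b_rev = np.frombuffer(reverse_complement(seq_b.upper()).encode(), dtype="S1")
    hits = _align_one_strand(a, b_fwd, query_id, target_id, False, k,
                             min_score, xdrop)
    hits += _align_one_strand(a, b_rev, query_id, target_id, True, k,
                              min_score, xdrop)
    return _dedupe_hits(hits)


def builtin_ani(seq_a: str, seq_b: str,
                min_identity: float = BLAST_MIN_IDENTITY,
                **aligner_kwargs) -> Optional[PairwiseANI]:
    """ANI/AF for one pair using the built-in aligner.

    ``min_identity`` mirrors the external search's identity floor; pass 0 to
    measure raw aligner recovery without the clustering prefilter.
    """
    hits = align_pair(seq_a, seq_b, **aligner_kwargs)
    return pairwise_ani(hits, len(seq_a), len(seq_b),
                        min_identity=min_identity)


# ---------------------------------------------------------------------------
# dereplication and greedy clustering

def dereplicate(records: Sequence[ContigRecord],
                reverse_complement_aware: bool = True) -> list[ContigRecord]:
    """Remove exact duplicates and exact substrings of longer sequences
    (100% identity over 100% of the shorter sequence).

    Assemblers emit either strand, so by default a sequence whose reverse
    complement is contained in a longer retained sequence is also removed.
    The longest representative of each identical group is retained; ties go
    to the lexicographically smaller id.
    """
    ordered = sorted(records, key=lambda r: (-r.length, r.id))
    retained: list[ContigRecord] = []
    for rec in ordered:
        seq = rec.sequence
        rc = reverse_complement(seq) if reverse_complement_aware else None
        duplicate = any(
            seq in keeper.sequence or (rc is not None and rc in keeper.sequence)
            for keeper in retained
        )
        if not duplicate:
            retained.append(rec)
    logger.info("dereplicate: %d -> %d sequences", len(records), len(retained))
    return sorted(retained, key=lambda r: r.id)


ANISource = Callable[[ContigRecord, ContigRecord], Optional[PairwiseANI]]


def builtin_ani_source(**aligner_kwargs) -> ANISource:
    def source(a: ContigRecord, b: ContigRecord) -> Optional[PairwiseANI]:
        return builtin_ani(a.sequence, b.sequence, query_id=a.id,
                           target_id=b.id, **aligner_kwargs)
    return source


def greedy_cluster(records: Sequence[ContigRecord], ani_source: ANISource,
                   min_ani: float = MIN_ANI,
                   min_af: float = MIN_AF) -> list[VOTU]:
    """Greedy centroid clustering at the species threshold.

    Genomes are sorted by decreasing length (ties by id); the longest
    unassigned genome becomes the centroid of a new cluster and every
    unassigned genome within ``min_ani``/``min_af`` of it (inclusive) is
    assigned; this repeats until all genomes are assigned. Members are never
    reassigned, so output is a partition and is invariant to input order.
    """
    ordered = sorted(records, key=lambda r: (-r.length, r.id))
    assigned: set[str] = set()
    clusters: list[VOTU] = []
    for centroid in ordered:
        if centroid.id in assigned:
            continue
        members = {centroid.id}
        assigned.add(centroid.id)
        for other in ordered:
            if other.id in assigned:
                continue
            pair = ani_source(centroid, other)
            if pair is not None and pair.ani >= min_ani and pair.af_shorter >= min_af:
                members.add(other.id)
                assigned.add(other.id)
        clusters.append(VOTU(representative_id=centroid.id,
                             member_ids=frozenset(members)))
    logger.info("greedy_cluster: %d genomes -> %d vOTUs",
                len(records), len(clusters))
    return clusters
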