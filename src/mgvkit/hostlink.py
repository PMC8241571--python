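"""Host prediction: linking viral genomes to prokaryotic host genomes.

Two complementary evidence types connect a virus to a host genome:

* CRISPR-spacer matches — a spacer from a host CRISPR array aligning to the
  virus (either strand) over at least 95% of the spacer length with at most
  one combined mismatch or gap.
* Genome sequence matches — a local alignment of at least 1 kb at >= 96%
  nucleotide identity between a (decontaminated) host contig and the virus.

Host contigs whose annotated host-region fraction is below 50% are removed
first: metagenome-assembled host genomes sometimes carry mis-binned viral
contigs, which would otherwise produce spurious self-links. Per virus, the
host lineage is the lowest taxonomic rank with >70% agreement across
connections (each connection counting once, regardless of evidence type).

CRISPR array detection is external; this module consumes array/spacer
tables, merging redundant arrays reported by multiple detectors.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .core import ContigRecord, SearchHit, TaxonomyLabel, HOST_RANKS, \
    reverse_complement
from .taxonomy import ProteinTaxCall, RankEvidence, consensus_taxonomy
from .votu import align_pair

logger = logging.getLogger(__name__)

SPACER_MAX_EDITS = 1
SPACER_MIN_COVERAGE = 0.95
GENOME_MATCH_MIN_LENGTH = 1000
GENOME_MATCH_MIN_IDENTITY = 96.0
HOST_FRACTION_MIN = 0.50
MIN_AGREEMENT = 0.70


@dataclass(frozen=True)
class Spacer:
    host_genome_id: str
    contig_id: str
    start: int  # 1-based inclusive, on the host contig
    end: int
    sequence: str
    source_tool: str = ""

    def __post_init__(self) -> None:
        if not (15 <= len(self.sequence) <= 100):
            raise ValueError(
                f"spacer {self.contig_id}:{self.start}: length "
                f"{len(self.sequence)} outside sanity bounds [15, 100]"
            )


@dataclass(frozen=True)
class CRISPRArray:
    host_genome_id: str
    contig_id: str
    start: int
    end: int
    spacers: tuple[Spacer, ...]
    source_tool: str = ""


@dataclass(frozen=True)
class Connection:
    virus_id: str
    host_genome_id: str
    evidence: str  # "spacer" or "genome_match"
    virus_start: int  # 1-based inclusive locus on the virus
    virus_end: int
    identity: Optional[float] = None  # genome matches
    edits: Optional[int] = None       # spacer matches


def merge_arrays(arrays: Sequence[CRISPRArray]) -> list[CRISPRArray]:
    """Merge redundant arrays (from multiple detectors) by coordinates.

    Arrays on the same contig with overlapping intervals become one array
    spanning their union; spacer sets are united with exact duplicates
    (same locus and sequence) collapsed.
    """
    by_contig: dict[tuple[str, str], list[CRISPRArray]] = {}
    for arr in arrays:
        by_contig.setdefault((arr.host_genome_id, arr.contig_id), []).append(arr)

    merged: list[CRISPRArray] = []
    for (genome, contig), group in sorted(by_contig.items()):
        group = sorted(group, key=lambda a: (a.start, a.end))
        current: Optional[CRISPRArray] = None
        for arr in group:
            if current is not None and arr.start <= current.end:
                spacers = _dedupe_spacers(current.spacers + arr.spacers)
                tools = ",".join(sorted(
                    (set(current.source_tool.split(",")) | {arr.source_tool})
                    - {""}
                ))
                current = CRISPRArray(
                    host_genome_id=genome, contig_id=contig,
                    start=current.start, end=max(current.end, arr.end),
                    spacers=spacers, source_tool=tools)
            else:
                if current is not None:
                    merged.append(current)
                current = arr
        if current is not None:
            merged.append(current)
    logger.info("merge_arrays: %d -> %d arrays", len(arrays), len(merged))
    return merged


def _dedupe_spacers(spacers: Sequence[Spacer]) -> tuple[Spacer, ...]:
    seen: set[tuple] = set()
    out = []
    for s in sorted(spacers, key=lambda s: (s.start, s.end, s.sequence)):
        key = (s.start, s.end, s.sequence)
        if key not in seen:
            seen.add(key)
            out.append(s)
    return tuple(out)


# ---------------------------------------------------------------------------
# spacer matching

def _exact_positions(genome: str, pattern: str) -> list[int]:
    positions = []
    at = genome.find(pattern)
    while at != -1:
        positions.append(at)
        at = genome.find(pattern, at + 1)
    return positions


def _one_substitution_positions(genome: np.ndarray, pattern: np.ndarray) -> list[int]:
    m = len(pattern)
    if len(genome) < m:
        return []
    windows = sliding_window_view(genome, m)
    mismatches = (windows != pattern).sum(axis=1)
    return [int(i) for i in np.nonzero(mismatches == 1)[0]]


def _core_matches(genome: str, genome_arr: np.ndarray,
                  core: str) -> list[tuple[int, int, int]]:
    """All (start0, matched_len_on_genome, edits) where ``core`` matches the
    genome with at most one edit, by direct enumeration of the edit types."""
    m = len(core)
    core_arr = np.frombuffer(core.encode(), dtype="S1")
    found: list[tuple[int, int, int]] = []
    for pos in _exact_positions(genome, core):
        found.append((pos, m, 0))
    for pos in _one_substitution_positions(genome_arr, core_arr):
        found.append((pos, m, 1))
    # one spacer base deleted: pattern of length m-1 matches exactly
    if m >= 2:
        deletion_patterns = {core[:i] + core[i + 1:] for i in range(m)}
        for pat in deletion_patterns:
            for pos in _exact_positions(genome, pat):
                found.append((pos, m - 1, 1))
    # one genome base inserted: genome window of length m+1 matches core
    # around a single skipped base (interior positions only; an end
    # insertion is just flanking sequence, not an edit)
    if len(genome) >= m + 1:
        windows = sliding_window_view(genome_arr, m + 1)
        for i in range(1, m):
            ok = (windows[:, :i] == core_arr[:i]).all(axis=1) & \
                 (windows[:, i + 1:] == core_arr[i:]).all(axis=1)
            for pos in np.nonzero(ok)[0]:
                found.append((int(pos), m + 1, 1))
    return found


def find_spacer_matches(spacer_seq: str, genome: ContigRecord,
                        max_edits: int = SPACER_MAX_EDITS,
                        min_coverage: float = SPACER_MIN_COVERAGE) -> list[tuple]:
    """All qualifying matches of one spacer against one viral genome.

    A match is an alignment of a spacer core — the spacer with at most
    ``floor((1 - min_coverage) * len)`` bases trimmed from its ends —
    containing at most ``max_edits`` combined mismatches/gaps, on either
    strand. Returns tuples ``(strand, virus_start, virus_end, edits)`` with
    1-based inclusive forward-strand coordinates, deduplicated to the best
    (fewest-edit, leftmost) match per overlapping locus.
    """
    m = len(spacer_seq)
    max_trim = int((1.0 - min_coverage) * m)
    spacer_seq = spacer_seq.upper()
    genome_fwd = genome.sequence.upper()
    n = len(genome_fwd)
    raw: list[tuple[str, int, int, int]] = []
    for strand, gseq in (("+", genome_fwd), ("-", reverse_complement(genome_fwd))):
        garr = np.frombuffer(gseq.encode(), dtype="S1")
        for trim_left in range(max_trim + 1):
            for trim_right in range(max_trim + 1 - trim_left):
                core = spacer_seq[trim_left : m - trim_right]
                for pos, glen, edits in _core_matches(gseq, garr, core):
                    if edits > max_edits:
                        continue
                    if strand == "+":
                        start, end = pos + 1, pos + glen
                    else:
                        start, end = n - pos - glen + 1, n - pos
                    raw.append((strand, start, end, edits))
    # collapse overlapping matches to the best representative
    raw.sort(key=lambda t: (t[3], t[1], t[2], t[0]))
    kept: list[tuple[str, int, int, int]] = []
    for cand in raw:
        if any(cand[1] <= k[2] and cand[2] >= k[1] for k in kept):
            continue
        kept.append(cand)
    return sorted(kept, key=lambda t: (t[1], t[2]))


def match_spacers(spacers: Sequence[Spacer],
                  viral_genomes: Sequence[ContigRecord],
                  max_edits: int = SPACER_MAX_EDITS,
                  min_coverage: float = SPACER_MIN_COVERAGE) -> list[Connection]:
    """CRISPR-spacer connections between host genomes and viral genomes."""
    connections: list[Connection] = []
    for spacer in spacers:
        for genome in viral_genomes:
            for strand, start, end, edits in find_spacer_matches(
                    spacer.sequence, genome, max_edits, min_coverage):
                connections.append(Connection(
                    virus_id=genome.id, host_genome_id=spacer.host_genome_id,
                    evidence="spacer", virus_start=start, virus_end=end,
                    edits=edits))
    logger.info("match_spacers: %d spacers x %d genomes -> %d connections",
                len(spacers), len(viral_genomes), len(connections))
    return connections


# ---------------------------------------------------------------------------
# genome sequence matches

def genome_match_from_hits(hits: Sequence[SearchHit],
                           host_genome_by_contig: Mapping[str, str],
                           min_length: int = GENOME_MATCH_MIN_LENGTH,
                           min_identity: float = GENOME_MATCH_MIN_IDENTITY
                           ) -> list[Connection]:
    """Connections from virus-vs-host alignment hits (query = virus)."""
    connections = []
    for h in hits:
        if h.alignment_length >= min_length and h.percent_identity >= min_identity:
            connections.append(Connection(
                virus_id=h.query_id,
                host_genome_id=host_genome_by_contig[h.target_id],
                evidence="genome_match", virus_start=h.qstart,
                virus_end=h.qend, identity=h.percent_identity))
    return connections


def genome_match(host_contigs: Sequence[ContigRecord],
                 viral_genomes: Sequence[ContigRecord],
                 host_genome_by_contig: Mapping[str, str],
                 min_length: int = GENOME_MATCH_MIN_LENGTH,
                 min_identity: float = GENOME_MATCH_MIN_IDENTITY
                 ) -> list[Connection]:
    """Built-in aligner path for small inputs (external search for scale)."""
    hits: list[SearchHit] = []
    for virus in viral_genomes:
        for contig in host_contigs:
            hits.extend(align_pair(virus.sequence, contig.sequence,
                                   query_id=virus.id, target_id=contig.id))
    return genome_match_from_hits(hits, host_genome_by_contig,
                                  min_length, min_identity)


def decontaminate_host_contigs(contigs: Sequence[ContigRecord],
                               host_fraction: Mapping[str, float],
                               min_fraction: float = HOST_FRACTION_MIN
                               ) -> list[ContigRecord]:
    """Drop host contigs whose host-region fraction is below 50%.

    Contigs without an annotation are conservatively retained (with a
    warning): decontamination must not silently discard genuine host
    sequence.
    """
    retained = []
    for contig in contigs:
        fraction = host_fraction.get(contig.id)
        if fraction is None:
            logger.warning("decontaminate: %s has no host-fraction annotation; "
                           "retained", contig.id)
            retained.append(contig)
        elif fraction >= min_fraction:
            retained.append(contig)
    logger.info("decontaminate: %d -> %d contigs", len(contigs), len(retained))
    return retained


def host_consensus(connections: Sequence[Connection],
                   host_lineages: Mapping[str, TaxonomyLabel],
                   min_agreement: float = MIN_AGREEMENT) -> TaxonomyLabel:
    """Per-virus host lineage: lowest rank with >70% agreement.

    Each connection counts once (spacer and genome-match evidence weigh
    equally). Reuses the consensus machinery from the taxonomy module with
    unit weights, the host rank ladder, and no protein-count minimums.
    """
    calls = []
    for i, conn in enumerate(connections):
        lineage = host_lineages.get(conn.host_genome_id)
        if lineage is None:
            continue
        evidence = {
            rank: RankEvidence(taxon=lineage.get(rank), lineage=lineage,
                               bit_score=1.0, percent_identity=100.0)
            for rank in HOST_RANKS if lineage.get(rank) is not None
        }
        calls.append(ProteinTaxCall(
            protein_id=f"connection_{i}", label=lineage, bit_score=1.0,
            percent_identity=100.0, rank_evidence=evidence))
    return consensus_taxonomy(calls, ranks=HOST_RANKS,
                              min_agreement=min_agreement, weighted=False,
                              apply_rank_minimums=False)
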