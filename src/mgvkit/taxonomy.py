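"""Taxonomy transfer from reference protein hits and per-genome consensus.

Each viral protein is searched against taxonomically annotated reference
proteins; the lineage of the top hit (by bit-score) is transferred to the
protein, per rank. When the top hit is unannotated at a rank, the first
subsequent hit whose bit-score is within 25% of the top hit (i.e. at least
0.75x) and which carries that rank supplies it.

A genome's consensus lineage is then the lowest (most specific) rank at
which more than 70% bit-score-weighted agreement exists among the proteins
annotated at that rank, subject to rank-specific minimum-evidence rules:
family requires at least two annotated proteins with >30% identity, genus
at least three annotated proteins with >40% average identity. More-general
ranks are inherited from the winning lineage.

The same consensus machinery serves host prediction with the prokaryotic
rank ladder and unit weights (see ``mgvkit.hostlink``).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

from .core import SearchHit, TaxonomyLabel, VIRUS_RANKS

logger = logging.getLogger(__name__)

FALLBACK_BITS_FRACTION = 0.75
MIN_AGREEMENT = 0.70
FAMILY_MIN_PROTEINS = 2
FAMILY_MIN_IDENTITY = 30.0
GENUS_MIN_PROTEINS = 3
GENUS_MIN_MEAN_IDENTITY = 40.0


@dataclass(frozen=True)
class RankEvidence:
    """The hit that supplied one rank of a protein's annotation."""
    taxon: str
    lineage: TaxonomyLabel  # full lineage of the supplying hit
    bit_score: float
    percent_identity: float


@dataclass
class ProteinTaxCall:
    protein_id: str
    label: TaxonomyLabel
    bit_score: float           # top hit's bit-score
    percent_identity: float    # top hit's percent identity
    rank_evidence: dict[str, RankEvidence] = field(default_factory=dict)


def filter_hits(hits: Sequence[SearchHit], query_length: int,
                target_lengths: Mapping[str, int],
                min_query_cover: float = 50.0, min_subject_cover: float = 50.0,
                max_evalue: float = 1e-5) -> list[SearchHit]:
    """Coverage / e-value prefilter matching the reference protein search."""
    kept = []
    for h in hits:
        qcov = 100.0 * (h.qend - h.qstart + 1) / query_length
        scov = 100.0 * (h.send - h.sstart + 1) / target_lengths[h.target_id]
        if qcov >= min_query_cover and scov >= min_subject_cover \
                and h.e_value <= max_evalue:
            kept.append(h)
    return kept


def transfer_protein_taxonomy(
    hits: Sequence[SearchHit],
    reference_taxonomy: Mapping[str, TaxonomyLabel],
    ranks: Sequence[str] = VIRUS_RANKS,
    fallback_fraction: float = FALLBACK_BITS_FRACTION,
) -> Optional[ProteinTaxCall]:
    """Transfer reference taxonomy to one protein from its ranked hits.

    ``hits`` must already satisfy the coverage and e-value prefilter
    (see :func:`filter_hits`). Per rank, the top hit's taxon is used; if
    missing there, the best subsequent hit carrying the rank with bit-score
    >= ``fallback_fraction`` x the top bit-score supplies it. Returns None
    when there are no hits.
    """
    if not hits:
        return None
    ordered = sorted(hits, key=lambda h: (-h.bit_score, h.target_id))
    top = ordered[0]
    floor = fallback_fraction * top.bit_score

    evidence: dict[str, RankEvidence] = {}
    for rank in ranks:
        for h in ordered:
            if h.bit_score < floor:
                break
            lineage = reference_taxonomy.get(h.target_id)
            if lineage is None:
                continue
            taxon = lineage.get(rank)
            if taxon is not None:
                evidence[rank] = RankEvidence(
                    taxon=taxon, lineage=lineage,
                    bit_score=h.bit_score, percent_identity=h.percent_identity)
                break

    label = TaxonomyLabel(
        {rank: ev.taxon for rank, ev in evidence.items()}, ladder=tuple(ranks))
    return ProteinTaxCall(protein_id=top.query_id, label=label,
                          bit_score=top.bit_score,
                          percent_identity=top.percent_identity,
                          rank_evidence=evidence)


def _rank_minimum_satisfied(rank: str, evidence: Sequence[RankEvidence]) -> bool:
    """Minimum-evidence rules applied per genome and rank."""
    if rank == "family":
        strong = [e for e in evidence if e.percent_identity > FAMILY_MIN_IDENTITY]
        return len(strong) >= FAMILY_MIN_PROTEINS
    if rank == "genus":
        if len(evidence) < GENUS_MIN_PROTEINS:
            return False
        mean_identity = sum(e.percent_identity for e in evidence) / len(evidence)
        return mean_identity > GENUS_MIN_MEAN_IDENTITY
    return True


def consensus_taxonomy(calls: Sequence[ProteinTaxCall],
                       ranks: Sequence[str] = VIRUS_RANKS,
                       min_agreement: float = MIN_AGREEMENT,
                       weighted: bool = True,
                       apply_rank_minimums: bool = True) -> TaxonomyLabel:
    """Genome-level lineage: lowest rank with >70% (weighted) agreement.

    Ranks are evaluated from most specific to most general. At each rank,
    agreement is the bit-score-weighted fraction of the modal taxon among
    proteins annotated at that rank (unannotated proteins are excluded from
    the denominator); modal ties break to the lexicographically smaller
    taxon with a warning. The first rank passing both the agreement
    threshold and its minimum-evidence rule wins, and all more-general
    ranks are inherited from the winning taxon's supporting lineage.
    Invariant under uniform scaling of bit-scores.
    """
    ladder = tuple(ranks)
    for rank in reversed(ladder):
        evidence = [
            c.rank_evidence[rank] for c in calls if rank in c.rank_evidence
        ]
        if not evidence:
            continue
        weights: dict[str, float] = {}
        for e in evidence:
            w = e.bit_score if weighted else 1.0
            weights[e.taxon] = weights.get(e.taxon, 0.0) + w
        total = sum(weights.values())
        top_weight = max(weights.values())
        modal_candidates = sorted(t for t, w in weights.items() if w == top_weight)
        if len(modal_candidates) > 1:
            logger.warning("consensus: modal-taxon tie at rank %s (%s); "
                           "choosing %s", rank, modal_candidates,
                           modal_candidates[0])
        modal = modal_candidates[0]
        if top_weight / total <= min_agreement:
            continue
        if apply_rank_minimums and not _rank_minimum_satisfied(rank, evidence):
            continue
        # inherit more-general ranks from the best supporting lineage
        supporting = sorted(
            (e for e in evidence if e.taxon == modal),
            key=lambda e: -e.bit_score)
        lineage = supporting[0].lineage.truncated(rank)
        result = dict(lineage.as_dict())
        result[rank] = modal
        return TaxonomyLabel(result, ladder=ladder)
    return TaxonomyLabel(ladder=ladder)
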