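"""Shared domain types for the viral cataloguing pipeline.

Coordinate convention: every interval in this package (gene calls, alignment
coordinates, spacer loci, provirus boundaries) is 1-based and inclusive at
both ends, matching GFF3 and tabular search output. The length of an interval
is therefore ``end - start + 1``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Optional

__all__ = [
    "ContigRecord",
    "GeneCall",
    "SearchHit",
    "TaxonomyLabel",
    "VIRUS_RANKS",
    "HOST_RANKS",
    "reverse_complement",
    "gc_content",
]

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

#: Virus-side rank ladder, most general -> most specific.
VIRUS_RANKS = ("baltimore", "order", "family", "genus")

#: Host-side (prokaryotic) rank ladder, most general -> most specific.
HOST_RANKS = ("domain", "phylum", "class", "order", "family", "genus", "species")


def reverse_complement(seq: str) -> str:
    """Reverse complement of a nucleotide string (case preserved, N -> N)."""
    return seq.translate(_COMPLEMENT)[::-1]


def gc_content(seq: str) -> float:
    """GC fraction computed over non-N bases; 0.0 for an all-N sequence."""
    s = seq.upper()
    acgt = sum(s.count(b) for b in "ACGT")
    if acgt == 0:
        return 0.0
    return (s.count("G") + s.count("C")) / acgt


@dataclass(frozen=True)
class ContigRecord:
    """A nucleotide sequence: the unit of classification and clustering.

    Attributes
    ----------
    id : str
        Unique identifier.
    sequence : str
        Nucleotide string over {A, C, G, T, N}.
    source_sample : str, optional
        Originating sample, carried through for provenance.
    """

    id: str
    sequence: str
    source_sample: Optional[str] = None

    def __post_init__(self) -> None:
        if len(self.sequence) < 1:
            raise ValueError(f"contig {self.id!r}: empty sequence")

    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def gc(self) -> float:
        return gc_content(self.sequence)

    def subsequence(self, start: int, end: int, id_suffix: str) -> "ContigRecord":
        """Inclusive 1-based subsequence as a new record with a suffixed id."""
        if not (1 <= start <= end <= self.length):
            raise ValueError(
                f"contig {self.id!r}: subsequence ({start}, {end}) out of range "
                f"for length {self.length}"
            )
        return replace(
            self, id=self.id + id_suffix, sequence=self.sequence[start - 1 : end]
        )


@dataclass(frozen=True)
class GeneCall:
    """A predicted protein-coding gene on a contig.

    ``coding_score`` is the gene caller's coding-potential score for the gene
    under ``genetic_code``; summing it per contig is how candidate genetic
    codes are compared.
    """

    contig_id: str
    gene_index: int  # 1-based ordinal along the contig
    start: int  # 1-based inclusive
    end: int  # 1-based inclusive
    strand: str  # "+" or "-"
    protein: str = ""
    coding_score: float = 0.0
    genetic_code: int = 11

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(
                f"gene {self.contig_id}:{self.gene_index}: invalid strand "
                f"{self.strand!r} (must be '+' or '-')"
            )
        if not (1 <= self.start <= self.end):
            raise ValueError(
                f"gene {self.contig_id}:{self.gene_index}: invalid coordinates "
                f"({self.start}, {self.end})"
            )

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class SearchHit:
    """One row of 12-column tabular alignment output.

    Raw tables may encode reverse-strand alignments as ``sstart > send``; on
    load the subject interval is normalised to (min, max) and the orientation
    recorded in ``subject_reversed``.
    """

    query_id: str
    target_id: str
    percent_identity: float
    alignment_length: int
    mismatches: int
    gap_opens: int
    qstart: int
    qend: int
    sstart: int
    send: int
    e_value: float
    bit_score: float
    subject_reversed: bool = False

    def __post_init__(self) -> None:
        if self.qstart > self.qend:
            raise ValueError(
                f"hit {self.query_id}->{self.target_id}: qstart > qend"
            )
        if self.sstart > self.send:
            raise ValueError(
                f"hit {self.query_id}->{self.target_id}: subject interval not "
                "normalised (sstart > send); use SearchHit.normalised()"
            )

    @classmethod
    def normalised(cls, query_id: str, target_id: str, percent_identity: float,
                   alignment_length: int, mismatches: int, gap_opens: int,
                   qstart: int, qend: int, sstart: int, send: int,
                   e_value: float, bit_score: float) -> "SearchHit":
        """Build a hit, normalising a reversed subject interval."""
        reversed_ = sstart > send
        if reversed_:
            sstart, send = send, sstart
        return cls(query_id, target_id, percent_identity, alignment_length,
                   mismatches, gap_opens, qstart, qend, sstart, send,
                   e_value, bit_score, subject_reversed=reversed_)


class TaxonomyLabel:
    """A ranked lineage: an ordered mapping of rank name -> taxon name.

    Works for both the virus ladder (baltimore/order/family/genus) and the
    host ladder (domain..species). Missing ranks are allowed anywhere; a
    lineage is prefix-consistent by construction because ranks are stored
    against a fixed ladder.
    """

    __slots__ = ("ranks", "ladder")

    def __init__(self, ranks: Optional[Mapping[str, str]] = None,
                 ladder: Iterable[str] = VIRUS_RANKS) -> None:
        self.ladder = tuple(ladder)
        self.ranks: dict[str, str] = {}
        if ranks:
            for rank, taxon in ranks.items():
                if rank not in self.ladder:
                    raise ValueError(f"unknown rank {rank!r} for ladder {self.ladder}")
                if taxon:
                    self.ranks[rank] = taxon

    def get(self, rank: str) -> Optional[str]:
        return self.ranks.get(rank)

    def is_empty(self) -> bool:
        return not self.ranks

    def lowest_rank(self) -> Optional[str]:
        """Most specific annotated rank, or None."""
        for rank in reversed(self.ladder):
            if rank in self.ranks:
                return rank
        return None

    def truncated(self, rank: str) -> "TaxonomyLabel":
        """Lineage restricted to ``rank`` and all more-general ranks."""
        idx = self.ladder.index(rank)
        keep = self.ladder[: idx + 1]
        return TaxonomyLabel({r: self.ranks[r] for r in keep if r in self.ranks},
                             ladder=self.ladder)

    def as_dict(self) -> dict[str, str]:
        return {r: self.ranks[r] for r in self.ladder if r in self.ranks}

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, TaxonomyLabel):
            return NotImplemented
        return self.ladder == other.ladder and self.ranks == other.ranks

    def __repr__(self) -> str:
        parts = ";".join(f"{r}={self.ranks[r]}" for r in self.ladder if r in self.ranks)
        return f"TaxonomyLabel({parts or 'unclassified'})"
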