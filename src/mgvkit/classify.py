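"""Multi-signature viral contig classification and the benchmark harness.

Four signatures separate viral from cellular contigs in bulk metagenome
assemblies: (1) counts of proteins whose best HMM hit is to a viral protein
family, (2) counts whose best hit is to a microbial family, (3) a nucleotide
composition score in [0, 1] from a pluggable scorer, and (4) the strand
switch rate — viral genes tend to run in long same-strand blocks, so a low
rate is a viral signal.

A rule set maps each benchmark fragment-length class to up to five threshold
clauses combined by disjunction; a contig is called viral when any clause is
satisfied. Clause boundaries are inclusive (``>=`` for minimums, ``<=`` for
maximums). The benchmark harness grid-searches clause thresholds against
labelled fragments, ranking by the classification score

    score = TPR - 50 * FPR

whose heavy false-positive penalty reflects that metagenomes are mostly
non-viral sequence.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

from .core import GeneCall

logger = logging.getLogger(__name__)

#: Benchmark fragment lengths in bp; a contig is assigned the largest class
#: <= its length, and contigs shorter than the smallest class are rejected.
BENCHMARK_LENGTHS = (1000, 2000, 5000, 10000, 20000, 50000, 100000)

FPR_WEIGHT = 50.0


@dataclass(frozen=True)
class ContigFeatures:
    """The four per-contig viral signatures plus bookkeeping counts."""

    contig_id: str
    n_genes: int
    n_viral_hits: int
    n_microbial_hits: int
    nt_score: float
    strand_switch_rate: float
    length: int

    def __post_init__(self) -> None:
        if self.n_viral_hits + self.n_microbial_hits > self.n_genes:
            raise ValueError(
                f"{self.contig_id}: labelled proteins exceed gene count"
            )
        if not (0.0 <= self.nt_score <= 1.0):
            raise ValueError(
                f"{self.contig_id}: nt_score {self.nt_score} outside [0, 1]"
            )


@dataclass(frozen=True)
class RuleClause:
    """A conjunction of signature thresholds; unset thresholds are ignored.

    Ordering of clauses (used for deterministic tie-breaks) is lexicographic
    on the threshold tuple with unset values sorting last.
    """

    min_viral_hits: Optional[int] = None
    max_microbial_hits: Optional[int] = None
    min_nt_score: Optional[float] = None
    max_strand_switch_rate: Optional[float] = None

    def __post_init__(self) -> None:
        if all(v is None for v in (self.min_viral_hits, self.max_microbial_hits,
                                   self.min_nt_score,
                                   self.max_strand_switch_rate)):
            raise ValueError("a rule clause must set at least one threshold")

    def __lt__(self, other: "RuleClause") -> bool:  # None sorts after values
        return self.sort_key() < other.sort_key()

    def sort_key(self) -> tuple:
        def k(v):
            return (1, 0.0) if v is None else (0, float(v))
        return (k(self.min_viral_hits), k(self.max_microbial_hits),
                k(self.min_nt_score), k(self.max_strand_switch_rate))

    def matches(self, f: ContigFeatures) -> bool:
        if self.min_viral_hits is not None and f.n_viral_hits < self.min_viral_hits:
            return False
        if (self.max_microbial_hits is not None
                and f.n_microbial_hits > self.max_microbial_hits):
            return False
        if self.min_nt_score is not None and f.nt_score < self.min_nt_score:
            return False
        if (self.max_strand_switch_rate is not None
                and f.strand_switch_rate > self.max_strand_switch_rate):
            return False
        return True


class RuleSet:
    """Per length class, an ordered disjunction of up to five clauses."""

    MAX_CLAUSES = 5

    def __init__(self, clauses_by_length: Mapping[int, Sequence[RuleClause]],
                 lengths: Sequence[int] = BENCHMARK_LENGTHS) -> None:
        self.lengths = tuple(sorted(lengths))
        self.clauses_by_length: dict[int, tuple[RuleClause, ...]] = {}
        for length, clauses in clauses_by_length.items():
            if length not in self.lengths:
                raise ValueError(f"unknown length class {length}")
            clauses = tuple(clauses)
            if not clauses:
                raise ValueError(f"length class {length}: empty clause list")
            if len(clauses) > self.MAX_CLAUSES:
                raise ValueError(
                    f"length class {length}: more than {self.MAX_CLAUSES} clauses"
                )
            self.clauses_by_length[length] = clauses

    def length_class(self, contig_length: int) -> int:
        """Largest benchmark length <= the contig length."""
        eligible = [c for c in self.lengths if c <= contig_length]
        if not eligible:
            raise ValueError(
                f"contig length {contig_length} below smallest class "
                f"{self.lengths[0]}"
            )
        return eligible[-1]

    def clauses_for(self, contig_length: int) -> tuple[RuleClause, ...]:
        cls = self.length_class(contig_length)
        # fall back to the nearest configured class at or below, then above
        if cls in self.clauses_by_length:
            return self.clauses_by_length[cls]
        configured = sorted(self.clauses_by_length)
        below = [c for c in configured if c <= cls]
        chosen = below[-1] if below else configured[0]
        return self.clauses_by_length[chosen]


#: Default rule set shipped as data. The published pipeline's tuned cutoffs
#: live in supplementary material not reproduced here; these defaults encode
#: the same qualitative logic (viral-family evidence, absence of microbial
#: families, nucleotide signal, same-strand gene blocks) and are meant to be
#: re-derived on any benchmark with `grid_search`.
def default_ruleset() -> RuleSet:
    clauses = (
        RuleClause(min_viral_hits=3, max_microbial_hits=1),
        RuleClause(min_viral_hits=1, max_microbial_hits=0, min_nt_score=0.60),
        RuleClause(max_microbial_hits=0, min_nt_score=0.90),
        RuleClause(min_viral_hits=5, max_strand_switch_rate=0.25),
        RuleClause(max_microbial_hits=1, min_nt_score=0.70,
                   max_strand_switch_rate=0.20),
    )
    return RuleSet({length: clauses for length in BENCHMARK_LENGTHS})


@dataclass(frozen=True)
class ClassificationMetrics:
    tpr: float   # percent of viral contigs called viral
    fpr: float   # percent of non-viral contigs called viral
    score: float # tpr - 50 * fpr

    def __post_init__(self) -> None:
        if not (0.0 <= self.tpr <= 100.0 and 0.0 <= self.fpr <= 100.0):
            raise ValueError("TPR/FPR must be percentages in [0, 100]")


def strand_switch_rate(genes: Sequence[GeneCall]) -> float:
    """Number of adjacent opposite-strand gene pairs divided by gene count.

    Zero for contigs with fewer than two genes. Input must be sorted by start.
    """
    n = len(genes)
    if n <= 1:
        return 0.0
    starts = [g.start for g in genes]
    if starts != sorted(starts):
        raise ValueError("genes must be sorted by start coordinate")
    switches = sum(
        1 for a, b in zip(genes, genes[1:]) if a.strand != b.strand
    )
    return switches / n


def classify_protein_hits(viral_hits: Sequence, microbial_hits: Sequence) -> str:
    """Label a protein by the database containing its top (bit-score) hit.

    Hits must be pre-filtered to e-value < 1e-10. Returns ``"viral"``,
    ``"microbial"`` or ``"none"``. A bit-score tie across databases resolves
    to viral: the pipeline is tuned for viral sensitivity, with specificity
    controlled downstream by the score's false-positive penalty.
    """
    best_viral = max((h.bit_score for h in viral_hits), default=None)
    best_microbial = max((h.bit_score for h in microbial_hits), default=None)
    if best_viral is None and best_microbial is None:
        return "none"
    if best_microbial is None:
        return "viral"
    if best_viral is None:
        return "microbial"
    return "viral" if best_viral >= best_microbial else "microbial"


def contig_features(contig_id: str, length: int, genes: Sequence[GeneCall],
                    per_protein_labels: Mapping[int, str],
                    nt_score: float) -> ContigFeatures:
    """Aggregate per-protein labels and gene strands into ContigFeatures.

    ``per_protein_labels`` maps gene_index -> {"viral", "microbial", "none"}.
    """
    if not (0.0 <= nt_score <= 1.0):
        raise ValueError(f"{contig_id}: nt_score {nt_score} outside [0, 1]")
    n_viral = sum(1 for v in per_protein_labels.values() if v == "viral")
    n_microbial = sum(1 for v in per_protein_labels.values() if v == "microbial")
    rate = strand_switch_rate(genes) if genes else 0.0
    return ContigFeatures(contig_id=contig_id, n_genes=len(genes),
                          n_viral_hits=n_viral, n_microbial_hits=n_microbial,
                          nt_score=nt_score, strand_switch_rate=rate,
                          length=length)


def evaluate(features: ContigFeatures, ruleset: RuleSet) -> bool:
    """True iff any clause of the contig's length class is satisfied."""
    return any(c.matches(features) for c in ruleset.clauses_for(features.length))


def compute_metrics(predictions: Mapping[str, bool],
                    truth_labels: Mapping[str, bool]) -> ClassificationMetrics:
    """TPR/FPR percentages and the weighted classification score."""
    if set(predictions) != set(truth_labels):
        raise ValueError("predictions and truth must cover the same contig ids")
    n_viral = sum(1 for v in truth_labels.values() if v)
    n_nonviral = len(truth_labels) - n_viral
    if n_viral == 0 or n_nonviral == 0:
        raise ValueError("truth must contain at least one contig of each class")
    tp = sum(1 for cid, t in truth_labels.items() if t and predictions[cid])
    fp = sum(1 for cid, t in truth_labels.items() if not t and predictions[cid])
    tpr = 100.0 * tp / n_viral
    fpr = 100.0 * fp / n_nonviral
    return ClassificationMetrics(tpr=tpr, fpr=fpr, score=tpr - FPR_WEIGHT * fpr)


@dataclass(frozen=True)
class RankedClause:
    clause: RuleClause
    metrics: ClassificationMetrics


def clause_grid(viral_hit_grid: Sequence[Optional[int]],
                microbial_hit_grid: Sequence[Optional[int]],
                nt_score_grid: Sequence[Optional[float]],
                switch_rate_grid: Sequence[Optional[float]]) -> list[RuleClause]:
    """Cartesian product of candidate thresholds as RuleClauses.

    ``None`` in a grid means the corresponding threshold is left unset; the
    all-None combination is skipped (an empty clause is invalid).
    """
    clauses = []
    for combo in itertools.product(viral_hit_grid, microbial_hit_grid,
                                   nt_score_grid, switch_rate_grid):
        if all(v is None for v in combo):
            continue
        clauses.append(RuleClause(*combo))
    return clauses


def grid_search(features: Sequence[ContigFeatures],
                truth_labels: Mapping[str, bool],
                grids: Mapping[str, Sequence],
                lengths: Sequence[int] = BENCHMARK_LENGTHS,
                max_clauses: int = 5) -> dict[int, list[RankedClause]]:
    """Exhaustively score every threshold combination per length class.

    ``grids`` carries candidate lists under the keys ``min_viral_hits``,
    ``max_microbial_hits``, ``min_nt_score``, ``max_strand_switch_rate``
    (each may include ``None`` = threshold unset). Returns, per length
    class, the ``max_clauses`` highest-scoring clauses; ties are broken by
    the clause's lexicographic threshold order for reproducibility.
    """
    clauses = clause_grid(grids.get("min_viral_hits", [None]),
                          grids.get("max_microbial_hits", [None]),
                          grids.get("min_nt_score", [None]),
                          grids.get("max_strand_switch_rate", [None]))
    if not clauses:
        raise ValueError("empty threshold grid")

    result: dict[int, list[RankedClause]] = {}
    lengths = tuple(sorted(lengths))
    for length_class in lengths:
        upper = next((l for l in lengths if l > length_class), None)
        members = [f for f in features
                   if f.length >= length_class
                   and (upper is None or f.length < upper)]
        if not members:
            continue
        truth = {f.contig_id: truth_labels[f.contig_id] for f in members}
        n_viral = sum(truth.values())
        if n_viral == 0 or n_viral == len(truth):
            logger.warning("grid_search: length class %d lacks both truth "
                           "classes; skipped", length_class)
            continue

        # vectorized clause evaluation over the fragment feature matrix
        fv = np.array([f.n_viral_hits for f in members])
        fm = np.array([f.n_microbial_hits for f in members])
        fn = np.array([f.nt_score for f in members])
        fs = np.array([f.strand_switch_rate for f in members])
        is_viral = np.array([truth[f.contig_id] for f in members], dtype=bool)
        nv, nn = int(is_viral.sum()), int((~is_viral).sum())

        ranked: list[tuple[float, RuleClause, ClassificationMetrics]] = []
        for clause in clauses:
            mask = np.ones(len(members), dtype=bool)
            if clause.min_viral_hits is not None:
                mask &= fv >= clause.min_viral_hits
            if clause.max_microbial_hits is not None:
                mask &= fm <= clause.max_microbial_hits
            if clause.min_nt_score is not None:
                mask &= fn >= clause.min_nt_score
            if clause.max_strand_switch_rate is not None:
                mask &= fs <= clause.max_strand_switch_rate
            tpr = 100.0 * float((mask & is_viral).sum()) / nv
            fpr = 100.0 * float((mask & ~is_viral).sum()) / nn
            metrics = ClassificationMetrics(tpr=tpr, fpr=fpr,
                                            score=tpr - FPR_WEIGHT * fpr)
            ranked.append((metrics.score, clause, metrics))

        ranked.sort(key=lambda t: (-t[0], t[1].sort_key()))
        result[length_class] = [RankedClause(clause=c, metrics=m)
                                for _, c, m in ranked[:max_clauses]]
        logger.info("grid_search: length %d: %d fragments, best score %.2f",
                    length_class, len(members),
                    result[length_class][0].metrics.score)
    return result


def ruleset_from_grid_search(selection: Mapping[int, Sequence[RankedClause]],
                             lengths: Sequence[int] = BENCHMARK_LENGTHS) -> RuleSet:
    return RuleSet({length: [r.clause for r in ranked]
                    for length, ranked in selection.items()},
                   lengths=lengths)
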