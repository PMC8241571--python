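"""Deterministic, seeded generators for every input class of the pipeline.

Every generator is a pure function of its arguments (including the seed):
the same call produces byte-identical output on any platform. Each
generator emits its planted ground truth alongside the data, so downstream
tests never re-derive truth from generator internals.

The fixtures emulate the statistical signatures the pipeline exploits —
same-strand gene runs, hit-label composition, substitution divergence,
recoded in-frame stops — rather than real viral sequence content: the
bespoke logic under test sits downstream of the external search tools.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .classify import BENCHMARK_LENGTHS, ContigFeatures
from .core import ContigRecord, reverse_complement
from .hostlink import Spacer

BASES = np.array(["A", "C", "G", "T"])

#: Codons that are a stop under at least one candidate genetic code.
_ALL_STOPS = {"TAA", "TAG", "TGA"}
_SENSE_CODONS = sorted(
    a + b + c
    for a in "ACGT" for b in "ACGT" for c in "ACGT"
    if a + b + c not in _ALL_STOPS
)


def _rng(seed: int) -> np.random.Generator:
    return np.random.default_rng(seed)


def random_sequence(length: int, rng: np.random.Generator,
                    gc: float = 0.5) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(rng.choice(BASES, size=length, p=p))


def mutate(sequence: str, divergence: float,
           rng: np.random.Generator) -> tuple[str, int]:
    """Apply i.i.d. substitutions at rate ``divergence``; every chosen site
    changes to a different base. Returns (mutant, true mutation count)."""
    if not (0.0 <= divergence < 0.3):
        raise ValueError("divergence must be in [0, 0.3)")
    arr = np.array(list(sequence))
    sites = np.nonzero(rng.random(len(arr)) < divergence)[0]
    for i in sites:
        choices = [b for b in "ACGT" if b != arr[i]]
        arr[i] = choices[rng.integers(3)]
    return "".join(arr), len(sites)


def gen_genome_pair(length: int, divergence: float, seed: int,
                    id_a: str = "genome_a", id_b: str = "genome_b"
                    ) -> tuple[ContigRecord, ContigRecord, int]:
    """A genome and a mutated copy of known substitution divergence."""
    rng = _rng(seed)
    seq_a = random_sequence(length, rng)
    seq_b, n_mut = mutate(seq_a, divergence, rng)
    return (ContigRecord(id=id_a, sequence=seq_a),
            ContigRecord(id=id_b, sequence=seq_b), n_mut)


# ---------------------------------------------------------------------------
# mock classification benchmark

VIRAL_CATEGORIES = ("crass_like", "lak_phage", "virome_phage",
                    "spacer_matched", "dsdna_human", "ssdna_human")
NONVIRAL_CATEGORIES = ("microbial", "plasmid")


@dataclass(frozen=True)
class BenchmarkSpec:
    """Stated world of the mock benchmark: 2,000 fragments per category at
    each of the seven fragment lengths, six viral and two non-viral
    categories. ``separable`` switches to a noiseless variant in which every
    viral fragment has >= 5 viral protein hits and no microbial hits, and
    every non-viral fragment has none — the regime where a correct grid
    search must reach a perfect score."""
    seed: int = 0
    n_per_category: int = 2000
    lengths: tuple = BENCHMARK_LENGTHS
    separable: bool = False


@dataclass
class MockBenchmark:
    features: list[ContigFeatures]
    truth: dict[str, bool]          # contig id -> is viral
    category: dict[str, str] = field(default_factory=dict)


def gen_mock_benchmark(spec: BenchmarkSpec) -> MockBenchmark:
    """Labelled fragment features for benchmarking the classifier.

    Viral fragments carry long same-strand gene runs (low strand switch
    rate), majority viral HMM labels and high nucleotide scores; non-viral
    fragments the opposite. Rates are drawn per fragment so the classes
    overlap realistically at short lengths, mirroring the difficulty of
    1 kb fragments, unless ``separable`` is set.
    """
    rng = _rng(spec.seed)
    features: list[ContigFeatures] = []
    truth: dict[str, bool] = {}
    category: dict[str, str] = {}
    for length in spec.lengths:
        for cat in VIRAL_CATEGORIES + NONVIRAL_CATEGORIES:
            is_viral = cat in VIRAL_CATEGORIES
            for i in range(spec.n_per_category):
                cid = f"{cat}_{length}_{i}"
                n_genes = max(1, int(rng.normal(length / 1000.0, 0.1 * length / 1000.0)))
                if spec.separable:
                    n_genes = max(n_genes, 6)
                    if is_viral:
                        n_viral = rng.integers(5, n_genes + 1)
                        n_microbial = 0
                        nt_score = float(rng.uniform(0.7, 1.0))
                        switches = rng.binomial(n_genes - 1, 0.02)
                    else:
                        n_viral = 0
                        n_microbial = rng.integers(1, n_genes + 1)
                        nt_score = float(rng.uniform(0.0, 0.3))
                        switches = rng.binomial(n_genes - 1, 0.4)
                elif is_viral:
                    n_viral = rng.binomial(n_genes, 0.6)
                    n_microbial = rng.binomial(n_genes - n_viral, 0.08)
                    nt_score = float(rng.beta(8, 2))
                    switches = rng.binomial(n_genes - 1, 0.05) if n_genes > 1 else 0
                else:
                    n_viral = rng.binomial(n_genes, 0.03)
                    n_microbial = rng.binomial(n_genes - n_viral, 0.7)
                    nt_score = float(rng.beta(2, 8))
                    switches = rng.binomial(n_genes - 1, 0.4) if n_genes > 1 else 0
                features.append(ContigFeatures(
                    contig_id=cid, n_genes=int(n_genes),
                    n_viral_hits=int(n_viral), n_microbial_hits=int(n_microbial),
                    nt_score=nt_score,
                    strand_switch_rate=float(switches) / n_genes,
                    length=length))
                truth[cid] = is_viral
                category[cid] = cat
    return MockBenchmark(features=features, truth=truth, category=category)


# ---------------------------------------------------------------------------
# provirus / terminal repeat fixtures

def gen_provirus(host_len: int, virus_len: int, dtr_len: int, seed: int,
                 contig_id: str = "provirus_contig"
                 ) -> tuple[ContigRecord, tuple[int, int]]:
    """A host contig with a planted viral region (optionally DTR-flanked).

    Returns the contig and the 1-based inclusive (viral_start, viral_end)
    boundaries of the planted virus. With ``dtr_len`` > 0 the viral region
    is R + core + R so the trimmed virus carries a direct terminal repeat.
    """
    if dtr_len and virus_len <= 2 * dtr_len:
        raise ValueError("virus_len must exceed twice dtr_len")
    rng = _rng(seed)
    if dtr_len > 0:
        repeat = random_sequence(dtr_len, rng)
        core = random_sequence(virus_len - 2 * dtr_len, rng)
        virus = repeat + core + repeat
    else:
        virus = random_sequence(virus_len, rng)
    left = random_sequence(host_len // 2, rng)
    right = random_sequence(host_len - host_len // 2, rng)
    sequence = left + virus + right
    start = len(left) + 1
    return (ContigRecord(id=contig_id, sequence=sequence),
            (start, start + virus_len - 1))


# ---------------------------------------------------------------------------
# CRISPR spacer plantings

@dataclass(frozen=True)
class PlantedSpacer:
    spacer: Spacer
    n_edits: int
    expect_hit: bool
    virus_start: int  # planted locus on the virus, 1-based inclusive
    virus_end: int


def plant_spacers(virus: ContigRecord, n: int, mismatches: int, seed: int,
                  spacer_len: int = 32, min_coverage: float = 0.95
                  ) -> list[PlantedSpacer]:
    """Spacers copied from random loci of a virus with planted mismatches.

    Mismatches are placed at interior spacer positions, clear of the ends by
    more than the coverage-trim allowance, so the expected outcome under the
    "<= 1 edit over >= 95% coverage" rule is exact: plantings with <= 1
    mismatch must be recovered and plantings with >= 2 must not. Half the
    spacers are taken from the reverse strand.
    """
    rng = _rng(seed)
    max_trim = int((1.0 - min_coverage) * spacer_len)
    lo = max_trim + 1          # 0-based interior band for edits
    hi = spacer_len - max_trim - 2
    if mismatches > 0 and hi - lo + 1 < mismatches:
        raise ValueError("spacer too short for requested interior mismatches")
    planted = []
    for i in range(n):
        start0 = int(rng.integers(0, virus.length - spacer_len + 1))
        segment = virus.sequence[start0 : start0 + spacer_len]
        arr = np.array(list(segment))
        sites = rng.choice(np.arange(lo, hi + 1), size=mismatches,
                           replace=False) if mismatches else []
        for site in sites:
            choices = [b for b in "ACGT" if b != arr[site]]
            arr[site] = choices[rng.integers(3)]
        spacer_seq = "".join(arr)
        if rng.random() < 0.5:
            spacer_seq = reverse_complement(spacer_seq)
        planted.append(PlantedSpacer(
            spacer=Spacer(host_genome_id=f"host_{i}",
                          contig_id=f"host_{i}_contig", start=100 * (i + 1),
                          end=100 * (i + 1) + spacer_len - 1,
                          sequence=spacer_seq, source_tool="synthetic"),
            n_edits=mismatches, expect_hit=mismatches <= 1,
            virus_start=start0 + 1, virus_end=start0 + spacer_len))
    return planted


# ---------------------------------------------------------------------------
# alternative genetic-code fixtures

_RECODED_STOP = {4: "TGA", 15: "TAG", 90: "TAA"}
#: Ends every gene under every candidate code within one codon or two.
_TERMINATOR = "TAATAGTGA"

#: Frame-blocker cassette: 16 sense codons (no in-frame stop under any
#: candidate code) whose five other readings — forward frames +1/+2 and all
#: three reverse-strand frames — each contain at least two distinct stop
#: triplet types near both ends. Interleaving it with short random-codon
#: segments bounds spurious out-of-frame ORFs under *every* candidate code,
#: so the naive ORF scorer's six-frame scan is not biased toward permissive
#: codes by frame noise.
_FRAME_BLOCKER = "TTAGGTAGTGCACTAGCATCAATGATAGACTATCAATTTTTTACTAAG"


def gen_recoded_genome(length: int, code: int, seed: int,
                       contig_id: str = "recoded", segments_per_gene: int = 6,
                       random_codons_per_segment: int = 8) -> ContigRecord:
    """A genome whose genes read through a reassigned stop codon.

    Genes are chains of segments, each built from AT-biased random sense
    codons (keeping GC below the 50% eligibility ceiling) followed by the
    frame-blocker cassette. For an alternative ``code`` the recoded stop is
    inserted at every interior segment boundary, so under the standard code
    each gene shatters into fragments too short for the naive ORF scorer's
    minimum, while under the true code the whole gene is one ORF. Every
    gene ends with a terminator carrying all three stop codons, so no
    candidate code reads through gene boundaries. ``code`` 11 produces the
    same construction without recoded stops.
    """
    if code not in (11, 4, 15, 90):
        raise ValueError(f"unknown genetic code {code}")
    rng = _rng(seed)
    # AT-biased codon choice keeps GC under the 50% eligibility ceiling
    weights = np.array([
        sum(2.0 if b in "AT" else 1.0 for b in codon) for codon in _SENSE_CODONS
    ])
    weights /= weights.sum()

    parts: list[str] = []
    total = 0
    while total < length:
        codons: list[str] = []
        for segment in range(segments_per_gene):
            if code != 11 and segment > 0:
                codons.append(_RECODED_STOP[code])
            codons.extend(rng.choice(_SENSE_CODONS,
                                     size=random_codons_per_segment, p=weights))
            codons.append(_FRAME_BLOCKER)
        gene = "".join(codons) + _TERMINATOR
        parts.append(gene)
        total += len(gene)
    sequence = "".join(parts)[:length]
    return ContigRecord(id=contig_id, sequence=sequence)


# ---------------------------------------------------------------------------
# planted vOTU clusters

@dataclass
class PlantedClusters:
    records: list[ContigRecord]
    truth: dict[str, int]  # genome id -> planted cluster index


def gen_planted_clusters(n_clusters: int = 3, members_per_cluster: int = 5,
                         length: int = 3000, within_divergence: float = 0.02,
                         between_divergence: float = 0.25,
                         seed: int = 0) -> PlantedClusters:
    """Genomes in well-separated clusters for clustering oracle tests.

    Cluster ancestors diverge from a common root at ``between_divergence``
    (pairwise far below any alignment-identity floor); members diverge from
    their ancestor at ``within_divergence`` so each member stays within the
    species thresholds of its cluster centroid.
    """
    rng = _rng(seed)
    root = random_sequence(length, rng)
    records: list[ContigRecord] = []
    truth: dict[str, int] = {}
    for c in range(n_clusters):
        ancestor, _ = mutate(root, between_divergence, rng)
        for m in range(members_per_cluster):
            seq, _ = mutate(ancestor, within_divergence, rng)
            cid = f"cluster{c}_member{m}"
            records.append(ContigRecord(id=cid, sequence=seq))
            truth[cid] = c
    return PlantedClusters(records=records, truth=truth)


# ---------------------------------------------------------------------------
# toy trees

def gen_toy_tree(n_tips: int, seed: int) -> str:
    """Random binary tree with branch lengths, as a newick string.

    Built by repeatedly joining two random subtrees; tip labels are
    ``t0..t{n-1}`` and branch lengths are uniform on (0.05, 1.05).
    """
    if n_tips < 2:
        raise ValueError("a tree needs at least two tips")
    rng = _rng(seed)
    nodes = [f"t{i}" for i in range(n_tips)]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        a, b = nodes[i], nodes[j]
        la, lb = rng.uniform(0.05, 1.05, size=2)
        joined = f"({a}:{la:.4f},{b}:{lb:.4f})"
        nodes = [n for idx, n in enumerate(nodes) if idx not in (i, j)]
        nodes.append(joined)
    return nodes[0] + ";"
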