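"""Genus- and family-level clustering from AAI and gene sharing.

Above the species rank, nucleotide identity saturates, so higher-rank
clusters are built from protein-level signals: for each genome pair the
average amino acid identity (AAI) over shared genes and the percentage of
genes shared. Pairs form a weighted graph — family-rank edges require
>= 20% AAI and >= 10% genes shared, genus-rank edges >= 50% AAI and >= 20%
shared — which is partitioned by Markov clustering (MCL) with inflation 1.2
at family rank and 2.0 at genus rank.

"Shared genes" are mutual best hits by bit-score (reciprocal best-hit
pairs), the standard AAI construction. The MCL edge weight is
``aai * shared_fraction / 100``, combining both signals; both choices are
configurable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import networkx as nx
import numpy as np

from .core import SearchHit

logger = logging.getLogger(__name__)

HIT_EVALUE_MAX = 1e-5

RANK_FILTERS = {
    # rank -> (min AAI %, min shared-gene %)
    "family": (20.0, 10.0),
    "genus": (50.0, 20.0),
}

RANK_INFLATION = {"family": 1.2, "genus": 2.0}


@dataclass(frozen=True)
class GenomePairAAI:
    genome_a: str
    genome_b: str
    aai: float              # mean percent identity over shared gene pairs
    shared_fraction: float  # percent of the smaller proteome shared
    n_shared: int


@dataclass(frozen=True)
class MCLParams:
    inflation: float = 2.0
    prune_threshold: float = 1e-5
    max_iterations: int = 100
    convergence_tol: float = 1e-6

    def __post_init__(self) -> None:
        if self.inflation <= 1.0:
            raise ValueError("MCL inflation must be > 1")


def compute_aai(protein_hits: Sequence[SearchHit], genome_a: str,
                genome_b: str, n_genes_a: int, n_genes_b: int,
                max_evalue: float = HIT_EVALUE_MAX) -> Optional[GenomePairAAI]:
    """AAI and shared-gene fraction from protein hits of genome a vs b.

    Shared genes are reciprocal best hits by bit-score among hits passing
    the e-value filter; ties resolve to the lexicographically smaller
    partner for determinism. Returns None when no genes are shared (no
    edge between the pair).
    """
    if n_genes_a <= 0 or n_genes_b <= 0:
        raise ValueError("both genomes must have at least one gene")
    hits = [h for h in protein_hits if h.e_value < max_evalue]
    if not hits:
        return None

    best_for_query: dict[str, SearchHit] = {}
    best_for_target: dict[str, SearchHit] = {}
    for h in hits:
        cur = best_for_query.get(h.query_id)
        if cur is None or (h.bit_score, cur.target_id) > (cur.bit_score, h.target_id):
            best_for_query[h.query_id] = h
        cur = best_for_target.get(h.target_id)
        if cur is None or (h.bit_score, cur.query_id) > (cur.bit_score, h.query_id):
            best_for_target[h.target_id] = h

    shared = [
        h for h in best_for_query.values()
        if best_for_target[h.target_id].query_id == h.query_id
    ]
    if not shared:
        return None
    aai = float(np.mean([h.percent_identity for h in shared]))
    fraction = 100.0 * len(shared) / min(n_genes_a, n_genes_b)
    return GenomePairAAI(genome_a=genome_a, genome_b=genome_b, aai=aai,
                         shared_fraction=min(100.0, fraction),
                         n_shared=len(shared))


def build_graph(pairs: Sequence[GenomePairAAI], rank: str) -> nx.Graph:
    """Weighted genome graph with rank-specific AAI / sharing filters."""
    if rank not in RANK_FILTERS:
        raise ValueError(f"rank must be one of {sorted(RANK_FILTERS)}")
    min_aai, min_shared = RANK_FILTERS[rank]
    graph = nx.Graph()
    kept = 0
    for p in pairs:
        graph.add_node(p.genome_a)
        graph.add_node(p.genome_b)
        if p.aai < min_aai or p.shared_fraction < min_shared:
            continue
        graph.add_edge(p.genome_a, p.genome_b,
                       weight=p.aai * p.shared_fraction / 100.0)
        kept += 1
    logger.info("build_graph[%s]: %d pairs -> %d edges kept", rank, len(pairs), kept)
    return graph


def mcl(graph: nx.Graph, params: Optional[MCLParams] = None) -> list[set]:
    """Markov clustering of a weighted graph.

    Standard formulation: the column-stochastic transition matrix (with unit
    self-loops) is alternately expanded (matrix squared) and inflated
    (entrywise power then column renormalisation, with entries below the
    prune threshold zeroed) until the iterate stabilises. Clusters are read
    off the attractors of the limit matrix; overlapping attractor supports
    are merged. Deterministic for a fixed node set.
    """
    if params is None:
        params = MCLParams()
    nodes = sorted(graph.nodes)
    if not nodes:
        return []
    index = {node: i for i, node in enumerate(nodes)}
    n = len(nodes)
    m = np.zeros((n, n))
    for a, b, data in graph.edges(data=True):
        w = float(data.get("weight", 1.0))
        m[index[a], index[b]] = w
        m[index[b], index[a]] = w
    # self-loops weighted like each node's strongest edge: a fixed unit loop
    # would be negligible next to heavy edges, leaving the random walk nearly
    # periodic and shattering two-node clusters
    loops = m.max(axis=0)
    loops[loops == 0.0] = 1.0
    np.fill_diagonal(m, loops)
    m /= m.sum(axis=0, keepdims=True)

    converged = False
    for _ in range(params.max_iterations):
        previous = m
        m = m @ m                                    # expansion
        m = np.power(m, params.inflation)            # inflation
        m[m < params.prune_threshold] = 0.0          # pruning
        colsums = m.sum(axis=0, keepdims=True)
        colsums[colsums == 0.0] = 1.0
        m /= colsums
        if previous.shape == m.shape and np.max(np.abs(m - previous)) < params.convergence_tol:
            converged = True
            break
    if not converged:
        logger.warning("mcl: no convergence after %d iterations; "
                       "interpreting last iterate", params.max_iterations)

    # attractor-based interpretation
    attractors = [i for i in range(n) if m[i, i] > 0.0]
    clusters: list[set] = []
    for i in attractors:
        support = {nodes[j] for j in np.nonzero(m[i] > 0.0)[0]}
        support.add(nodes[i])
        merged = [c for c in clusters if c & support]
        for c in merged:
            support |= c
            clusters.remove(c)
        clusters.append(support)
    clustered = set().union(*clusters) if clusters else set()
    for node in nodes:  # isolated / non-attracted nodes become singletons
        if node not in clustered:
            clusters.append({node})
    return sorted(clusters, key=lambda c: sorted(c)[0])


def cluster_rank(pairs: Sequence[GenomePairAAI], rank: str,
                 params: Optional[MCLParams] = None) -> list[set]:
    """Filter edges for ``rank`` and partition with the rank's inflation."""
    if params is None:
        params = MCLParams(inflation=RANK_INFLATION[rank])
    return mcl(build_graph(pairs, rank), params)


def cluster_homogeneity(clusters: Sequence[set],
                        reference_labels: Mapping[str, str]) -> tuple[float, float]:
    """Agreement between a clustering and reference taxon labels.

    Returns ``(homogeneity, cohesion)`` in percent: homogeneity is the mean
    over clusters of the fraction of labelled members carrying the modal
    taxon; cohesion is the mean over taxa of the fraction of that taxon's
    genomes placed in its modal cluster. Unlabelled genomes are ignored.
    """
    labelled_clusters = []
    for cluster in clusters:
        labels = [reference_labels[g] for g in cluster if g in reference_labels]
        if labels:
            labelled_clusters.append(labels)
    if not labelled_clusters:
        raise ValueError("no labelled genomes in any cluster")

    homogeneity = float(np.mean([
        max(labels.count(t) for t in set(labels)) / len(labels)
        for labels in labelled_clusters
    ])) * 100.0

    by_taxon: dict[str, list[int]] = {}
    for ci, cluster in enumerate(clusters):
        for g in cluster:
            if g in reference_labels:
                by_taxon.setdefault(reference_labels[g], []).append(ci)
    cohesion = float(np.mean([
        max(assignments.count(c) for c in set(assignments)) / len(assignments)
        for assignments in by_taxon.values()
    ])) * 100.0
    return homogeneity, cohesion
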