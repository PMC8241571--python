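"""Phylogenetic utilities: marker concatenation, diversity, core-SNP matrices.

Tree inference itself is delegated to an external approximate-ML tool; this
module owns the surrounding arithmetic:

* per-marker alignment trimming (drop columns with >= 50% gaps) and
  concatenation over a fixed marker order, gap-filling missing markers;
* the inclusion filter (a genome needs >= 3 markers and data at > 5% of
  alignment columns);
* phylogenetic diversity (PD) of a genome subset — the sum of branch
  lengths of every branch with at least one subset tip among its
  descendants on the (midpoint-)rooted tree, so PD of all tips equals the
  total branch length;
* midpoint rooting;
* core-genome SNP matrices from alignments of cluster members to the
  longest member (positions covered by >= 50% of genomes, genomes with
  data at >= 50% of retained positions; substitutions only, N/gap missing).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence, Union

import dendropy
import pandas as pd

logger = logging.getLogger(__name__)

GAP_CHARS = frozenset("-.")
MISSING_CHARS = frozenset("-.Nn")

MAX_GAP_FRACTION = 0.50
MIN_MARKERS = 3
MIN_COLUMN_FRACTION = 0.05
SNP_MIN_POSITION_COVERAGE = 0.50
SNP_MIN_GENOME_COVERAGE = 0.50


@dataclass
class MarkerAlignment:
    """One marker's aligned sequences: genome id -> gap-padded row."""

    marker_id: str
    sequences: dict[str, str]

    def __post_init__(self) -> None:
        lengths = {len(s) for s in self.sequences.values()}
        if len(lengths) > 1:
            raise ValueError(f"marker {self.marker_id}: ragged alignment")

    @property
    def n_columns(self) -> int:
        return len(next(iter(self.sequences.values()))) if self.sequences else 0


def trim_columns(alignment: MarkerAlignment,
                 max_gap_fraction: float = MAX_GAP_FRACTION) -> MarkerAlignment:
    """Remove columns whose gap fraction is >= ``max_gap_fraction``.

    Retains positions with *less than* 50% gaps by default.
    """
    if not alignment.sequences:
        raise ValueError(f"marker {alignment.marker_id}: empty alignment")
    rows = list(alignment.sequences.values())
    n_rows = len(rows)
    keep = [
        col for col in range(alignment.n_columns)
        if sum(1 for row in rows if row[col] in GAP_CHARS) / n_rows
        < max_gap_fraction
    ]
    trimmed = {
        genome: "".join(row[c] for c in keep)
        for genome, row in alignment.sequences.items()
    }
    return MarkerAlignment(marker_id=alignment.marker_id, sequences=trimmed)


def concatenate(markers: Sequence[MarkerAlignment],
                genome_ids: Iterable[str]
                ) -> tuple[dict[str, str], dict[str, int]]:
    """Concatenate trimmed markers over a fixed marker order.

    Genomes missing a marker receive an all-gap block of that marker's
    width. Returns the concatenated rows and per-genome marker counts.
    """
    genome_ids = list(genome_ids)
    if not genome_ids:
        raise ValueError("empty genome set")
    rows = {g: [] for g in genome_ids}
    counts = {g: 0 for g in genome_ids}
    for marker in markers:
        width = marker.n_columns
        for g in genome_ids:
            if g in marker.sequences:
                rows[g].append(marker.sequences[g])
                counts[g] += 1
            else:
                rows[g].append("-" * width)
    return {g: "".join(parts) for g, parts in rows.items()}, counts


def filter_genomes(rows: Mapping[str, str], marker_counts: Mapping[str, int],
                   min_markers: int = MIN_MARKERS,
                   min_column_fraction: float = MIN_COLUMN_FRACTION
                   ) -> list[str]:
    """Genomes with >= ``min_markers`` markers and data at more than
    ``min_column_fraction`` of alignment columns."""
    kept = []
    for genome, row in rows.items():
        if marker_counts.get(genome, 0) < min_markers:
            continue
        if not row:
            continue
        non_gap = sum(1 for c in row if c not in GAP_CHARS) / len(row)
        if non_gap > min_column_fraction:
            kept.append(genome)
    logger.info("filter_genomes: %d -> %d genomes", len(rows), len(kept))
    return sorted(kept)


# ---------------------------------------------------------------------------
# trees

def read_tree(source: str, is_path: bool = True) -> dendropy.Tree:
    kwargs = {"path": source} if is_path else {"data": source}
    return dendropy.Tree.get(schema="newick", **kwargs)


def phylogenetic_diversity(tree: dendropy.Tree,
                           tip_subset: Iterable[str]) -> float:
    """Sum of branch lengths represented by a set of tips.

    A branch is represented when at least one subset tip descends from it
    on the rooted tree; with the full tip set this is the total branch
    length. The empty subset has PD 0.
    """
    subset = set(tip_subset)
    if not subset:
        return 0.0
    tip_names = {leaf.taxon.label for leaf in tree.leaf_node_iter()}
    unknown = subset - tip_names
    if unknown:
        raise ValueError(f"subset tips not in tree: {sorted(unknown)}")

    total = 0.0
    represented: dict[int, bool] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            rep = node.taxon.label in subset
        else:
            rep = any(represented[id(c)] for c in node.child_nodes())
        represented[id(node)] = rep
        if rep and node.edge.length is not None and node.parent_node is not None:
            total += node.edge.length
    return total


def total_branch_length(tree: dendropy.Tree) -> float:
    return sum(e.length for e in tree.preorder_edge_iter()
               if e.length is not None and e.head_node.parent_node is not None)


def midpoint_root(tree: dendropy.Tree) -> dendropy.Tree:
    """Root the tree at the midpoint of its longest tip-to-tip path."""
    if len(tree.leaf_nodes()) < 2:
        raise ValueError("midpoint rooting needs at least two tips")
    if total_branch_length(tree) == 0.0:
        raise ValueError("cannot midpoint-root a zero-length tree")
    rooted = tree.clone(depth=1)
    rooted.is_rooted = True
    rooted.reroot_at_midpoint(update_bipartitions=True)
    return rooted


# ---------------------------------------------------------------------------
# core-genome SNP matrices

@dataclass
class SNPMatrix:
    """Genome x position allele matrix (reference coordinates, 1-based).

    ``data`` holds single-character alleles with missing entries as NaN.
    """

    data: pd.DataFrame  # index: genome ids; columns: 1-based positions

    @property
    def positions(self) -> list[int]:
        return list(self.data.columns)

    @property
    def genomes(self) -> list[str]:
        return list(self.data.index)


def core_snp_matrix(aligned: Mapping[str, str],
                    min_position_coverage: float = SNP_MIN_POSITION_COVERAGE,
                    min_genome_coverage: float = SNP_MIN_GENOME_COVERAGE
                    ) -> SNPMatrix:
    """SNP matrix from alignments of all genomes to the longest member.

    ``aligned`` maps genome id -> a reference-coordinate string (one char
    per reference position: the genome's base there, or '-'/'N' when
    missing). Positions covered by >= 50% of genomes and showing at least
    two alleles are retained (substitutions only — indels and N are
    missing data); then genomes with data at >= 50% of retained positions
    are kept, in that order.
    """
    if len(aligned) < 2:
        raise ValueError("core SNP matrix requires at least two genomes")
    lengths = {len(s) for s in aligned.values()}
    if len(lengths) != 1:
        raise ValueError("all rows must share reference coordinates")
    n_ref = lengths.pop()
    genomes = sorted(aligned)
    n_genomes = len(genomes)

    positions = []
    columns = {}
    for pos in range(n_ref):
        alleles = {
            g: aligned[g][pos].upper()
            for g in genomes if aligned[g][pos] not in MISSING_CHARS
        }
        if len(alleles) / n_genomes < min_position_coverage:
            continue
        if len(set(alleles.values())) < 2:
            continue  # invariant position
        positions.append(pos + 1)
        columns[pos + 1] = alleles

    frame = pd.DataFrame(
        {pos: {g: columns[pos].get(g) for g in genomes} for pos in positions},
        index=genomes, dtype=object)
    if positions:
        coverage = frame.notna().sum(axis=1) / len(positions)
        frame = frame.loc[coverage >= min_genome_coverage]
    logger.info("core_snp_matrix: %d genomes, %d variant positions retained",
                frame.shape[0], frame.shape[1])
    return SNPMatrix(data=frame)
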