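"""Independent oracles used to cross-check the package's implementations.

Each oracle deliberately takes a different computational path from the code
it validates: full dynamic-programming alignment instead of seeded ungapped
extension, path enumeration instead of subtree bookkeeping, exhaustive loops
instead of vectorised evaluation.
"""

from __future__ import annotations

import itertools

from Bio import Align


def dp_local_identity(seq_a: str, seq_b: str) -> float:
    """Percent identity of the best full-DP local alignment.

    Smith-Waterman with match +1 / mismatch -1 and strongly penalised gaps
    (the generators plant substitutions only); identity is computed over all
    alignment columns including gaps.
    """
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = 1
    aligner.mismatch_score = -1
    aligner.open_gap_score = -5
    aligner.extend_gap_score = -2
    alignment = aligner.align(seq_a, seq_b)[0]
    counts = alignment.counts()
    columns = counts.identities + counts.mismatches + counts.gaps
    return 100.0 * counts.identities / columns


def _edit_distance_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 0
    aligner.mismatch_score = -1
    aligner.open_gap_score = -1
    aligner.extend_gap_score = -1
    aligner.end_deletion_score = 0  # free genome flanks: semi-global
    return aligner


_EDIT_ALIGNER = _edit_distance_aligner()


def semi_global_edits(pattern: str, text: str) -> int:
    """Minimum edit distance of ``pattern`` to any substring of ``text``."""
    return int(round(-_EDIT_ALIGNER.score(text, pattern)))


def spacer_hit_oracle(spacer: str, genome: str, revcomp, max_edits: int = 1,
                      min_coverage: float = 0.95) -> bool:
    """Brute-force spacer-match decision by full DP over every trim/strand.

    A hit exists when some end-trimmed core of the spacer covering at least
    ``min_coverage`` of its length aligns to either strand within
    ``max_edits`` combined substitutions/indels.
    """
    m = len(spacer)
    max_trim = int((1.0 - min_coverage) * m)
    for strand_seq in (genome, revcomp(genome)):
        for a in range(max_trim + 1):
            for b in range(max_trim + 1 - a):
                core = spacer[a : m - b]
                if semi_global_edits(core, strand_seq) <= max_edits:
                    return True
    return False


def brute_force_grid_maximum(features, truth, clauses, fpr_weight=50.0):
    """Best clause score by plain exhaustive loops (no vectorisation)."""
    best = None
    for clause in clauses:
        tp = fp = nv = nn = 0
        for f in features:
            viral = truth[f.contig_id]
            nv += viral
            nn += not viral
            if clause.matches(f):
                tp += viral
                fp += not viral
        score = 100.0 * tp / nv - fpr_weight * 100.0 * fp / nn
        if best is None or score > best:
            best = score
    return best


def pd_path_union(tree, tip_subset) -> float:
    """Phylogenetic diversity as the union of root-to-tip edge paths."""
    subset = set(tip_subset)
    edges = set()
    for leaf in tree.leaf_node_iter():
        if leaf.taxon.label not in subset:
            continue
        node = leaf
        while node.parent_node is not None:
            edges.add(id(node.edge))
            node = node.parent_node
    total = 0.0
    for edge in tree.preorder_edge_iter():
        if id(edge) in edges and edge.length is not None:
            total += edge.length
    return total


def connected_components(graph) -> list[set]:
    """Component partition by naive flood fill (oracle for clique MCL)."""
    seen: set = set()
    components = []
    for start in sorted(graph.nodes):
        if start in seen:
            continue
        stack, comp = [start], set()
        while stack:
            node = stack.pop()
            if node in comp:
                continue
            comp.add(node)
            stack.extend(n for n in graph.neighbors(node) if n not in comp)
        seen |= comp
        components.append(comp)
    return sorted(components, key=lambda c: sorted(c)[0])
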