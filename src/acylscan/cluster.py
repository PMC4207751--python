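"""Distance-based clustering of validated hits into subfamily clades.

Pairwise distances are one minus the identity fraction of the global
(Needleman-Wunsch) alignment under BLOSUM62 with affine gaps 11/1; a
Poisson correction ``-ln(1 - d)`` is available for sensitivity checks.
Trees are built by neighbor joining with a deterministic lexicographic
tie-break, and clade membership is decided by exact bipartition lookup on
the unrooted tree.  Only clade structure is interpreted downstream; no
support values are computed.
"""

from __future__ import annotations

import math
from typing import Iterable, Mapping

import dendropy
import numpy as np
from skbio import DistanceMatrix

from .survey import SurveyParams, _aligner


def pairwise_distances(
    seqs: Mapping[str, str],
    params: SurveyParams = SurveyParams(),
    correction: str = "none",
) -> DistanceMatrix:
    """Identity-based distance matrix over a set of sequences.

    ``correction="poisson"`` applies ``-ln(1 - d)`` (capped at distance
    0.999 to stay finite).
    """
    if len(seqs) < 2:
        raise ValueError("need at least two sequences")
    for name, seq in seqs.items():
        if not seq:
            raise ValueError(f"empty sequence {name!r}")
    if correction not in ("none", "poisson"):
        raise ValueError(f"unknown correction {correction!r}")
    ids = list(seqs)
    aligner = _aligner(
        "global", params.matrix_name, params.gap_open, params.gap_extend
    )
    n = len(ids)
    matrix = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            alignment = aligner.align(seqs[ids[i]], seqs[ids[j]])[0]
            counts = alignment.counts()
            columns = counts.identities + counts.mismatches + counts.gaps
            identity = counts.identities / columns if columns else 0.0
            d = 1.0 - identity
            if correction == "poisson":
                d = -math.log(1.0 - min(d, 0.999))
            matrix[i, j] = matrix[j, i] = d
    return DistanceMatrix(matrix, ids)


def _as_distance_matrix(D) -> DistanceMatrix:
    if isinstance(D, DistanceMatrix):
        return D
    raise ValueError("expected a skbio DistanceMatrix")


def neighbor_joining(D: DistanceMatrix) -> str:
    """Neighbor-joining tree as a Newick string.

    Ties in the Q-criterion are broken toward the lexicographically
    smallest (id, id) pair so the result is independent of input order.
    Negative branch lengths are clamped to zero with the deficit moved to
    the sister branch, preserving the path length between the joined
    taxa.
    """
    D = _as_distance_matrix(D)
    ids = list(D.ids)
    if len(ids) < 3:
        raise ValueError("neighbor joining needs at least three taxa")
    dist: dict[tuple[str, str], float] = {}
    for i, a in enumerate(ids):
        for j, b in enumerate(ids):
            dist[(a, b)] = float(D[i, j])
    newick: dict[str, str] = {name: name for name in ids}
    # sort key of a node: smallest leaf label under it, for tie-breaks
    leafkey: dict[str, str] = {name: name for name in ids}
    active = sorted(ids)
    counter = 0

    def fmt(length: float) -> str:
        return f"{max(length, 0.0):.6f}"

    while len(active) > 3:
        r = len(active)
        totals = {a: sum(dist[(a, b)] for b in active if b != a)
                  for a in active}
        best_q = math.inf
        best_pair: tuple[str, str] | None = None
        for a, b in (
            (x, y) for i, x in enumerate(active) for y in active[i + 1:]
        ):
            q = (r - 2) * dist[(a, b)] - totals[a] - totals[b]
            pair_key = tuple(sorted((leafkey[a], leafkey[b])))
            if q < best_q - 1e-12 or (
                abs(q - best_q) <= 1e-12
                and best_pair is not None
                and pair_key < tuple(
                    sorted((leafkey[best_pair[0]], leafkey[best_pair[1]]))
                )
            ):
                best_q, best_pair = q, (a, b)
        a, b = best_pair
        la = 0.5 * dist[(a, b)] + (totals[a] - totals[b]) / (2 * (r - 2))
        lb = dist[(a, b)] - la
        # clamp negatives, shifting the deficit to the sister branch
        if la < 0:
            lb += la
            la = 0.0
        if lb < 0:
            la += lb
            lb = 0.0
        counter += 1
        node = f"__node{counter}"
        first, second = sorted((a, b), key=lambda x: leafkey[x])
        lengths = {a: la, b: lb}
        newick[node] = (
            f"({newick[first]}:{fmt(lengths[first])},"
            f"{newick[second]}:{fmt(lengths[second])})"
        )
        leafkey[node] = min(leafkey[a], leafkey[b])
        for c in active:
            if c in (a, b):
                continue
            dist[(node, c)] = dist[(c, node)] = 0.5 * (
                dist[(a, c)] + dist[(b, c)] - dist[(a, b)]
            )
        dist[(node, node)] = 0.0
        active = sorted(
            [c for c in active if c not in (a, b)] + [node],
            key=lambda x: leafkey[x],
        )

    a, b, c = active
    la = 0.5 * (dist[(a, b)] + dist[(a, c)] - dist[(b, c)])
    lb = 0.5 * (dist[(a, b)] + dist[(b, c)] - dist[(a, c)])
    lc = 0.5 * (dist[(a, c)] + dist[(b, c)] - dist[(a, b)])
    parts = sorted(zip((a, b, c), (la, lb, lc)), key=lambda p: leafkey[p[0]])
    return (
        "(" + ",".join(f"{newick[n]}:{fmt(v)}" for n, v in parts) + ");"
    )


def _load_tree(tree: str | dendropy.Tree) -> dendropy.Tree:
    if isinstance(tree, dendropy.Tree):
        return tree
    return dendropy.Tree.get(data=tree, schema="newick")


def tree_splits(tree: str | dendropy.Tree) -> set[frozenset[str]]:
    """Non-trivial bipartitions of an unrooted tree, each reported as the
    smaller-or-lexicographic side's leaf set."""
    t = _load_tree(tree)
    taxa = frozenset(leaf.taxon.label for leaf in t.leaf_node_iter())
    splits: set[frozenset[str]] = set()
    for node in t.preorder_node_iter():
        if node.parent_node is None or node.is_leaf():
            continue
        side = frozenset(
            leaf.taxon.label for leaf in node.leaf_iter()
        )
        if 1 < len(side) < len(taxa) - 1:
            other = taxa - side
            splits.add(min(side, other, key=lambda s: (len(s), sorted(s))))
    return splits


def is_clade(tree: str | dendropy.Tree, labels: Iterable[str]) -> bool:
    """Whether some edge of the unrooted tree separates ``labels`` exactly
    from all remaining taxa."""
    t = _load_tree(tree)
    taxa = frozenset(leaf.taxon.label for leaf in t.leaf_node_iter())
    labels = frozenset(labels)
    unknown = labels - taxa
    if unknown:
        raise ValueError(f"labels not in tree: {sorted(unknown)}")
    if len(labels) <= 1 or len(taxa - labels) <= 1:
        return True  # trivial bipartitions always exist
    other = taxa - labels
    wanted = min(labels, other, key=lambda s: (len(s), sorted(s)))
    return wanted in tree_splits(t)
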