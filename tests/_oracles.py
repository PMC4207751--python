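"""Independent brute-force oracles used by the test suite.

These deliberately avoid the implementation's algorithms: local
alignment is scored by exhaustive enumeration over all monotone residue
pairings (quartic in sequence length, no affine gap state machine), and
motif chains are enumerated combinatorially.
"""

from __future__ import annotations

from itertools import product

import numpy as np
from Bio.Align import substitution_matrices

from acylscan.scan import DBM_PENALTY, occurrence_table

_B62 = substitution_matrices.load("BLOSUM62")


def sw_oracle(a: str, b: str, gap_open: int = 11, gap_extend: int = 1) -> float:
    """Best local alignment score by enumeration over aligned-pair chains.

    Every local alignment is a strictly increasing chain of aligned
    residue pairs; unpaired residues between consecutive pairs form gap
    runs costing ``gap_open + len * gap_extend`` each.  Enumerating all
    predecessor pairs for every pair is exhaustive and independent of
    the affine-gap dynamic program it checks.
    """
    n, m = len(a), len(b)
    best = 0.0
    end = [[0.0] * m for _ in range(n)]
    for i in range(n):
        for j in range(m):
            pair = float(_B62[a[i], b[j]])
            best_prev = 0.0
            for ip in range(i):
                for jp in range(j):
                    di, dj = i - ip - 1, j - jp - 1
                    gap = 0.0
                    if di > 0:
                        gap += gap_open + di * gap_extend
                    if dj > 0:
                        gap += gap_open + dj * gap_extend
                    best_prev = max(best_prev, end[ip][jp] - gap)
            end[i][j] = pair + best_prev
            best = max(best, end[i][j])
    return best


def chain_oracle(seq, prof, dbm_mode="soft"):
    """Best full motif chain by exhaustive combination of occurrences.

    Returns ``(score, placements)`` or ``None``; ties broken like the
    scanner: highest score, then smallest placement tuple.
    """
    occs = occurrence_table(prof, seq)
    if any(not occ for occ in occs):
        return None
    best = None
    for combo in product(*occs):
        ok = True
        for k in range(3):
            off, length, _ = combo[k]
            noff = combo[k + 1][0]
            if noff < off + length:
                ok = False
                break
        if not ok:
            continue
        score = sum(c[2] for c in combo)
        rejected = False
        for k in range(3):
            d = combo[k + 1][0] - (combo[k][0] + combo[k][1])
            lo, hi = prof.dbm_ranges[k]
            if not lo <= d <= hi:
                if dbm_mode == "hard":
                    rejected = True
                    break
                excess = (lo - d) if d < lo else (d - hi)
                score -= DBM_PENALTY * excess
        if rejected:
            continue
        placements = tuple((c[0], c[1]) for c in combo)
        key = (-score, placements)
        if best is None or key < best[0]:
            best = (key, score, placements)
    if best is None:
        return None
    return best[1], best[2]


def random_additive_tree(n_taxa: int, rng: np.random.Generator):
    """A random tree with positive branch lengths and its additive
    leaf-to-leaf distances, built by random agglomeration."""
    nodes = [(f"t{i}", {f"t{i}": 0.0}) for i in range(n_taxa)]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), 2, replace=False))
        (na, da), (nb, db) = nodes[i], nodes[j]
        ba = float(rng.uniform(0.05, 1.0))
        bb = float(rng.uniform(0.05, 1.0))
        merged = {k: v + ba for k, v in da.items()}
        merged.update({k: v + bb for k, v in db.items()})
        newick = f"({na}:{ba:.5f},{nb}:{bb:.5f})"
        nodes = [
            nodes[k] for k in range(len(nodes)) if k not in (i, j)
        ] + [(newick, merged)]
    newick, _ = nodes[0]
    import dendropy

    tree = dendropy.Tree.get(data=newick + ";", schema="newick")
    pdm = tree.phylogenetic_distance_matrix()
    taxa = sorted(tree.taxon_namespace, key=lambda t: t.label)
    ids = [t.label for t in taxa]
    mat = np.array([[pdm.distance(x, y) for y in taxa] for x in taxa])
    return newick + ";", ids, mat
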