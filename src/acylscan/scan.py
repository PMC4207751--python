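"""Locate ordered motif I-IV chains on a protein under spacing constraints.

The distance between motifs (DBM) counts the residues strictly between
the last residue of the upstream motif and the first residue of the
downstream one.  A chain's score is the sum of the specificity weights of
all matched pattern positions plus a spacing term: zero when a DBM falls
inside the profile's interval, and in ``soft`` mode a penalty of
``-0.5`` per residue outside it (``hard`` mode discards such chains
outright).  The best chain is found by dynamic programming over the
per-motif occurrence lists; on small inputs it provably equals exhaustive
enumeration of all in-order, non-overlapping motif combinations.
"""

from __future__ import annotations

from dataclasses import dataclass

from .grammar import scored_matches_at
from .profiles import SubclassProfile

#: soft-mode penalty per residue of DBM violation
DBM_PENALTY = 0.5


@dataclass(frozen=True)
class MotifChain:
    """One placement of (a subset of) motifs I-IV on a protein.

    ``placements[k]`` is an ``(offset, length)`` pair or ``None`` when
    motif k was skipped (partial chains).  ``dbm[k]`` is the residue count
    strictly between motifs k and k+1, defined only when both are placed.
    """

    placements: tuple[tuple[int, int] | None, ...]
    dbm: tuple[int | None, ...]
    score: float

    def __post_init__(self) -> None:
        if len(self.placements) != 4 or len(self.dbm) != 3:
            raise ValueError("a chain covers four motifs and three gaps")
        end = -1
        for placement in self.placements:
            if placement is None:
                continue
            off, length = placement
            if off < end:
                raise ValueError("motif placements overlap or are unordered")
            end = off + length

    @property
    def n_placed(self) -> int:
        return sum(1 for p in self.placements if p is not None)

    @property
    def is_full(self) -> bool:
        return self.n_placed == 4


def occurrence_table(
    prof: SubclassProfile, seq: str
) -> list[list[tuple[int, int, float]]]:
    """Per-motif lists of ``(offset, length, match_score)`` occurrences."""
    table: list[list[tuple[int, int, float]]] = []
    for pattern in prof.motifs:
        occ = []
        for i in range(len(seq) + 1):
            for length, score in sorted(
                scored_matches_at(pattern, seq, i).items()
            ):
                occ.append((i, length, score))
        table.append(occ)
    return table


def _dbm_term(
    d: int, lo: int, hi: int, mode: str
) -> float | None:
    """Spacing contribution; ``None`` marks a hard-mode rejection."""
    if lo <= d <= hi:
        return 0.0
    excess = (lo - d) if d < lo else (d - hi)
    if mode == "hard":
        return None
    return -DBM_PENALTY * excess


def scan_chain(
    seq: str,
    prof: SubclassProfile,
    dbm_mode: str = "soft",
    min_motifs: int = 4,
    dbm_convention: str = "strict",
) -> MotifChain | None:
    """Best-scoring in-order, non-overlapping chain of motifs I-IV.

    Parameters
    ----------
    seq:
        Protein sequence (uppercase one-letter codes).
    prof:
        Subclass profile supplying the four patterns and DBM intervals.
    dbm_mode:
        ``soft`` penalises out-of-range spacing, ``hard`` rejects it.
    min_motifs:
        Minimum number of motifs a chain must place (3 allows partial
        chains in which one motif is skipped; spacing across a skipped
        motif is unconstrained).
    dbm_convention:
        ``strict`` counts residues strictly between motifs (the default
        and the convention of the shipped intervals); ``inclusive`` also
        counts the two boundary residues, for sensitivity checks.

    Returns ``None`` when no chain with ``min_motifs`` motifs exists (or
    none survives hard-mode filtering).
    """
    if not seq:
        raise ValueError("empty sequence")
    if dbm_mode not in ("soft", "hard"):
        raise ValueError(f"unknown dbm_mode {dbm_mode!r}")
    if dbm_convention not in ("strict", "inclusive"):
        raise ValueError(f"unknown dbm_convention {dbm_convention!r}")
    if not 1 <= min_motifs <= 4:
        raise ValueError("min_motifs must be in 1..4")
    shift = 2 if dbm_convention == "inclusive" else 0
    max_skips = 4 - min_motifs
    occs = occurrence_table(prof, seq)

    # DP state: (motif index k, occurrence j, skips used so far).  Each
    # state keeps the best (score, tie-break chain) over admissible
    # predecessors; skip count is part of the state because chains with
    # different skip budgets are not interchangeable for later transitions.
    Entry = tuple[float, tuple[tuple[int, int, int], ...]]
    # entry = (score, ((motif, off, len), ...))
    best: dict[tuple[int, int, int], Entry] = {}

    def better(a: Entry, b: Entry | None) -> bool:
        # max score; ties -> more motifs placed, then smallest placements
        if b is None:
            return True
        return (-a[0], 4 - len(a[1]), a[1]) < (-b[0], 4 - len(b[1]), b[1])

    for k in range(4):
        for j, (off, length, mscore) in enumerate(occs[k]):
            # start a chain at motif k (k leading skips)
            if k <= max_skips:
                cand: Entry = (mscore, ((k, off, length),))
                if better(cand, best.get((k, j, k))):
                    best[(k, j, k)] = cand
            # extend from any placed predecessor motif
            for kp in range(k):
                skipped_between = k - kp - 1
                for jp, (poff, plen, _) in enumerate(occs[kp]):
                    pend = poff + plen
                    if off < pend:
                        continue
                    if skipped_between == 0:
                        d = off - pend + shift
                        lo, hi = prof.dbm_ranges[kp]
                        term = _dbm_term(d, lo + shift, hi + shift, dbm_mode)
                        if term is None:
                            continue
                        gap_score = term
                    else:
                        gap_score = 0.0
                    for s in range(max_skips + 1 - skipped_between):
                        prev = best.get((kp, jp, s))
                        if prev is None:
                            continue
                        cand = (
                            prev[0] + mscore + gap_score,
                            prev[1] + ((k, off, length),),
                        )
                        state = (k, j, s + skipped_between)
                        if better(cand, best.get(state)):
                            best[state] = cand

    final: Entry | None = None
    for (k, _j, s), entry in sorted(best.items()):
        if s + (3 - k) > max_skips:
            continue
        if better(entry, final):
            final = entry
    if final is None:
        return None

    placements: list[tuple[int, int] | None] = [None] * 4
    for k, off, length in final[1]:
        placements[k] = (off, length)
    dbm: list[int | None] = [None] * 3
    for k in range(3):
        a, b = placements[k], placements[k + 1]
        if a is not None and b is not None:
            dbm[k] = b[0] - (a[0] + a[1]) + shift
    score = final[0]
    return MotifChain(tuple(placements), tuple(dbm), score)


def compute_dbm(
    chain: MotifChain, dbm_convention: str = "strict"
) -> tuple[int, int, int]:
    """The three inter-motif distances of a full chain, in order I-II,
    II-III, III-IV."""
    if not chain.is_full:
        raise ValueError("DBM requires all four motifs placed")
    shift = 2 if dbm_convention == "inclusive" else 0
    out = []
    for k in range(3):
        off_a, len_a = chain.placements[k]
        off_b, _ = chain.placements[k + 1]
        d = off_b - (off_a + len_a)
        if d < 0:
            raise ValueError(f"motifs {k + 1} and {k + 2} overlap")
        out.append(d + shift)
    return tuple(out)


def hx_spacing(seq: str, chain: MotifChain) -> int:
    """Residues strictly between the motif-I histidine and aspartate.

    The fungal microsomal GPATs carry five residues between the catalytic
    H and D (HX5D); all other subclasses carry four (HX4D).
    """
    if chain.placements[0] is None:
        raise ValueError("chain does not place motif I")
    off, length = chain.placements[0]
    window = seq[off:off + length]
    if len(window) < 2 or window[0] != "H" or window[-1] != "D":
        raise ValueError(
            f"motif-I window {window!r} lacks the terminal H/D dyad"
        )
    return length - 2
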