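"""Degenerate motif grammar: parse, serialize, match and derive patterns.

A motif pattern is a space-delimited string of tokens.  Each token denotes
one position:

* a single literal residue (``H``),
* ``x`` — any of the 20 standard residues,
* ``φ`` (or ``phi``) — hydrophobic V, I, L, F, W, Y, M,
* ``π`` (or ``pi``) — short-chain P, G, A, S,
* ``[+]`` — positively charged K, R, H,
* a bracketed alternative ``[A/B/...]`` whose alternatives are literals,
  class symbols, or ``-`` meaning the position may be absent (the position
  becomes optional and the motif length varies by one).

Hallmark positions — the residues that diagnostically define each motif,
such as the catalytic H and D of motif I — are not part of the pattern
string; they are supplied separately (the shipped profile fixtures carry
them as position indices).
"""

from __future__ import annotations

from dataclasses import dataclass
from math import log2
from typing import Iterable, Sequence

from .alphabet import AA_SET, PHI, PI, plus_class

MOTIF_LABELS = ("I", "II", "III", "IV")

_CLASS_TOKENS = {"φ": PHI, "phi": PHI, "π": PI, "pi": PI}


class PatternError(ValueError):
    """Raised for malformed motif pattern strings."""


@dataclass(frozen=True)
class PositionSpec:
    """One position of a degenerate motif pattern."""

    allowed: frozenset[str]
    hallmark: bool = False
    optional: bool = False
    token: str = "x"

    def __post_init__(self) -> None:
        if not self.allowed or not self.allowed <= AA_SET:
            raise PatternError(
                f"allowed set must be a non-empty subset of the 20 standard "
                f"residues, got {sorted(self.allowed)}"
            )
        if self.optional and self.hallmark:
            raise PatternError("an optional position cannot be a hallmark")

    @property
    def is_wildcard(self) -> bool:
        return self.allowed == AA_SET

    def matches(self, residue: str) -> bool:
        """Whether ``residue`` satisfies this position.

        Residues outside the 20-letter alphabet (B, Z, X, U, ...) match
        only the full wildcard: degenerate residues are never allowed to
        stand in for a specific or hallmark requirement.
        """
        if residue in AA_SET:
            return residue in self.allowed
        return self.is_wildcard

    @property
    def weight(self) -> float:
        """Specificity weight in bits: log2(20 / |allowed|)."""
        return log2(20.0 / len(self.allowed))


@dataclass(frozen=True)
class MotifPattern:
    """An ordered sequence of :class:`PositionSpec`, labelled I-IV."""

    positions: tuple[PositionSpec, ...]
    label: str
    source_text: str = ""

    def __post_init__(self) -> None:
        if self.label not in MOTIF_LABELS:
            raise PatternError(f"motif label must be one of {MOTIF_LABELS}")
        if not self.positions:
            raise PatternError("empty pattern")

    def __len__(self) -> int:
        return len(self.positions)

    @property
    def n_optional(self) -> int:
        return sum(1 for p in self.positions if p.optional)

    @property
    def min_length(self) -> int:
        return len(self.positions) - self.n_optional

    @property
    def max_score(self) -> float:
        return sum(p.weight for p in self.positions)

    def hallmark_positions(self) -> tuple[int, ...]:
        return tuple(i for i, p in enumerate(self.positions) if p.hallmark)


def _parse_token(token: str, column: int) -> PositionSpec:
    if token == "x":
        return PositionSpec(AA_SET, token="x")
    if token in _CLASS_TOKENS:
        return PositionSpec(_CLASS_TOKENS[token], token=token)
    if token == "[+]":
        return PositionSpec(plus_class(), token="[+]")
    if len(token) == 1 and token in AA_SET:
        return PositionSpec(frozenset(token), token=token)
    if token.startswith("[") and token.endswith("]") and "/" in token:
        alts = token[1:-1].split("/")
        allowed: set[str] = set()
        optional = False
        for alt in alts:
            if alt == "-":
                optional = True
            elif alt in _CLASS_TOKENS:
                allowed |= _CLASS_TOKENS[alt]
            elif alt == "+":
                allowed |= plus_class()
            elif len(alt) == 1 and alt in AA_SET:
                allowed.add(alt)
            else:
                raise PatternError(
                    f"unknown alternative {alt!r} in token {token!r} "
                    f"(column {column})"
                )
        if not allowed:
            raise PatternError(
                f"token {token!r} (column {column}) allows no residue"
            )
        return PositionSpec(frozenset(allowed), optional=optional, token=token)
    raise PatternError(f"unknown token {token!r} (column {column})")


def parse_pattern(
    text: str,
    label: str = "I",
    hallmark: Iterable[int] = (),
) -> MotifPattern:
    """Parse a space-delimited degenerate pattern string.

    Parameters
    ----------
    text:
        Pattern string, e.g. ``"H x N Q F φ D"``.
    label:
        Motif label, one of ``I``-``IV``.
    hallmark:
        0-based indices of hallmark positions.
    """
    tokens = text.split()
    if not tokens:
        raise PatternError("empty pattern")
    hallmark = frozenset(hallmark)
    bad = [i for i in hallmark if not 0 <= i < len(tokens)]
    if bad:
        raise PatternError(f"hallmark index out of range: {sorted(bad)}")
    positions = []
    for col, tok in enumerate(tokens):
        spec = _parse_token(tok, col)
        if col in hallmark:
            if spec.optional:
                raise PatternError(
                    f"optional position {col} cannot be a hallmark"
                )
            spec = PositionSpec(
                spec.allowed, hallmark=True, optional=False, token=spec.token
            )
        positions.append(spec)
    return MotifPattern(tuple(positions), label=label, source_text=text)


def serialize(pattern: MotifPattern) -> str:
    """Inverse of :func:`parse_pattern` (up to the hallmark annotation)."""
    return " ".join(p.token for p in pattern.positions)


def match_at(pattern: MotifPattern, seq: str, i: int) -> set[int]:
    """Lengths L such that ``seq[i:i+L]`` satisfies the pattern at offset i.

    Optional positions contribute both the skipped and the matched branch,
    so up to ``2 ** n_optional`` distinct lengths can be returned.
    """
    if not 0 <= i <= len(seq):
        raise ValueError(f"offset {i} outside sequence of length {len(seq)}")
    return {length for length, _ in _placements(pattern, seq, i)}


def scored_matches_at(
    pattern: MotifPattern, seq: str, i: int
) -> dict[int, float]:
    """Map match length -> specificity score of the best branch.

    The score of a placement is the sum of position weights
    ``log2(20/|allowed|)`` over matched (non-skipped) positions.
    """
    best: dict[int, float] = {}
    for length, score in _placements(pattern, seq, i):
        if length not in best or score > best[length]:
            best[length] = score
    return best


def _placements(
    pattern: MotifPattern, seq: str, i: int
) -> list[tuple[int, float]]:
    out: list[tuple[int, float]] = []

    def rec(pos_idx: int, offset: int, score: float) -> None:
        if pos_idx == len(pattern.positions):
            out.append((offset - i, score))
            return
        spec = pattern.positions[pos_idx]
        if spec.optional:
            rec(pos_idx + 1, offset, score)
        if offset < len(seq) and spec.matches(seq[offset]):
            rec(pos_idx + 1, offset + 1, score + spec.weight)

    rec(0, i, 0.0)
    return out


def find_occurrences(
    pattern: MotifPattern, seq: str
) -> list[tuple[int, int]]:
    """All ``(offset, length)`` matches, sorted by offset then length."""
    hits = []
    for i in range(len(seq) + 1):
        for length in sorted(match_at(pattern, seq, i)):
            hits.append((i, length))
    return hits


def derive_consensus(
    instances: Sequence[str],
    max_alts: int,
    label: str = "I",
) -> MotifPattern:
    """Build a degenerate pattern from aligned equal-length motif instances.

    Column rules, applied in order: a single residue becomes a literal;
    a column contained in the short-chain class becomes ``π``; one
    contained in the hydrophobic class becomes ``φ``; at most ``max_alts``
    distinct residues become a bracketed alternative (alphabetical);
    anything else becomes the wildcard ``x``.
    """
    if len(instances) < 2:
        raise PatternError("need at least two instances")
    length = len(instances[0])
    for inst in instances:
        if len(inst) != length:
            raise PatternError(
                f"length mismatch: expected {length}, got {len(inst)} "
                f"({inst!r})"
            )
        if not set(inst) <= AA_SET:
            raise PatternError(f"non-standard residue in {inst!r}")
    tokens = []
    for col in range(length):
        residues = {inst[col] for inst in instances}
        if len(residues) == 1:
            tokens.append(next(iter(residues)))
        elif residues <= PI:
            tokens.append("π")
        elif residues <= PHI:
            tokens.append("φ")
        elif len(residues) <= max_alts:
            tokens.append("[" + "/".join(sorted(residues)) + "]")
        else:
            tokens.append("x")
    return parse_pattern(" ".join(tokens), label=label)
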