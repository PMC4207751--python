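"""Peroxisomal targeting signal type 1 (PTS1) detection.

PTS1 is a C-terminal tripeptide (canonically SKL-like) that directs
proteins into the peroxisome.  The classifier here is a rule-based
tripeptide tier check: the ``canonical`` tier is ``[S/A/C][K/R/H][L/M]``,
the ``relaxed`` tier additionally admits G, P, T at position -3 and I, F
at position -1.  It depends on nothing but the final three residues and
is a deliberate desk-scale simplification of position-weight PTS1
predictors.
"""

from __future__ import annotations

from dataclasses import dataclass

_CANONICAL = (frozenset("SAC"), frozenset("KRH"), frozenset("LM"))
_RELAXED = (frozenset("SACGPT"), frozenset("KRH"), frozenset("LMIF"))


@dataclass(frozen=True)
class PTS1Call:
    """Result of the tripeptide check on one protein."""

    tripeptide: str
    positive: bool
    tier: str  # canonical | relaxed | none


def detect_pts1(seq: str) -> PTS1Call:
    """Classify the C-terminal tripeptide of ``seq``."""
    tri = seq[-3:]
    if len(tri) < 3:
        return PTS1Call(tripeptide=tri, positive=False, tier="none")
    if all(tri[i] in _CANONICAL[i] for i in range(3)):
        return PTS1Call(tripeptide=tri, positive=True, tier="canonical")
    if all(tri[i] in _RELAXED[i] for i in range(3)):
        return PTS1Call(tripeptide=tri, positive=True, tier="relaxed")
    return PTS1Call(tripeptide=tri, positive=False, tier="none")
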