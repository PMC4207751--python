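"""Amino-acid alphabet and residue-class definitions.

The degenerate motif notation uses three residue classes besides literal
residues and the ``x`` wildcard:

``pi``
    Short-chain residues P, G, A, S.
``phi``
    Hydrophobic residues V, I, L, F, W, Y, M.
``[+]``
    Positively charged / chargeable residues K, R, H.  Histidine is
    included because the motif contexts where the symbol occurs are basic
    and His is protonatable at physiological pH.  The membership is
    overridable via :func:`set_plus_class` for sensitivity analyses.
"""

from __future__ import annotations

AA20: str = "ACDEFGHIKLMNPQRSTVWY"
AA_SET: frozenset[str] = frozenset(AA20)

PI: frozenset[str] = frozenset("PGAS")
PHI: frozenset[str] = frozenset("VILFWYM")

#: default membership of the "[+]" class; module-level so config can override
_PLUS: frozenset[str] = frozenset("KRH")

#: Robinson & Robinson (1991) amino-acid frequencies, the composition most
#: protein-statistics software assumes.  Offered as an alternative to the
#: uniform default of the synthetic generator.
ROBINSON_FREQS: dict[str, float] = {
    "A": 0.07805, "C": 0.01925, "D": 0.05364, "E": 0.06295, "F": 0.03856,
    "G": 0.07377, "H": 0.02199, "I": 0.05142, "K": 0.05744, "L": 0.09019,
    "M": 0.02243, "N": 0.04487, "P": 0.05203, "Q": 0.04264, "R": 0.05129,
    "S": 0.07120, "T": 0.05841, "V": 0.06441, "W": 0.01330, "Y": 0.03216,
}


def plus_class() -> frozenset[str]:
    """Current membership of the ``[+]`` residue class."""
    return _PLUS


def set_plus_class(residues: str) -> None:
    """Override the ``[+]`` class membership (e.g. ``"KR"``)."""
    global _PLUS
    members = frozenset(residues.upper())
    if not members or not members <= AA_SET:
        raise ValueError(f"invalid [+] class membership: {residues!r}")
    _PLUS = members


def background_composition(name: str = "uniform") -> dict[str, float]:
    """Named background composition: ``uniform`` or ``robinson``."""
    if name == "uniform":
        return {aa: 1.0 / 20.0 for aa in AA20}
    if name == "robinson":
        total = sum(ROBINSON_FREQS.values())
        return {aa: f / total for aa, f in ROBINSON_FREQS.items()}
    raise ValueError(f"unknown background composition: {name!r}")
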