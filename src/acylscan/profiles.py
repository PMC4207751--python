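"""Subclass profiles: four motif patterns plus inter-motif spacing ranges.

The shipped fixtures describe the six opisthokont GPAT/DHAPAT subclasses:
the two fungal-type microsomal GPAT clades (fGPAT-A, which contains yeast
Sct1/Gpt2, and fGPAT-B), the metazoan ER-associated GPATs (eGPAT), the
mitochondrial GPATs, the fungal GDPATs (the pre-duplication clade related
to both mitoGPATs and DHAPATs) and the peroxisomal DHAPATs.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass
from pathlib import Path

import yaml

from .grammar import MotifPattern, parse_pattern

SUBCLASS_ORDER = (
    "fGPAT-A",
    "fGPAT-B",
    "eGPAT",
    "mitoGPAT",
    "fGDPAT",
    "DHAPAT",
)

#: subclasses whose motif I separates the catalytic H and D by 5 residues
HX5D_SUBCLASSES = frozenset({"fGPAT-A", "fGPAT-B"})
#: subclasses with the 4-residue spacing
HX4D_SUBCLASSES = frozenset(SUBCLASS_ORDER) - HX5D_SUBCLASSES


@dataclass(frozen=True)
class SubclassProfile:
    """Motif patterns I-IV and DBM intervals for one subclass."""

    subclass: str
    motifs: tuple[MotifPattern, MotifPattern, MotifPattern, MotifPattern]
    dbm_ranges: tuple[tuple[int, int], tuple[int, int], tuple[int, int]]
    dbm_exceptions: tuple[tuple[str, tuple[int, ...]], ...] = ()

    def __post_init__(self) -> None:
        if len(self.motifs) != 4:
            raise ValueError("a profile needs exactly four motifs")
        for lo, hi in self.dbm_ranges:
            if lo < 0 or lo > hi:
                raise ValueError(f"invalid DBM interval [{lo}, {hi}]")

    @property
    def hx_spacing(self) -> int:
        """Residues between the motif-I H and D implied by the pattern."""
        return len(self.motifs[0]) - 2

    @property
    def max_score(self) -> float:
        return sum(m.max_score for m in self.motifs)

    @property
    def min_core_length(self) -> int:
        """Shortest sequence stretch a full motif chain can occupy."""
        return sum(m.min_length for m in self.motifs) + sum(
            lo for lo, _ in self.dbm_ranges
        )


def _profile_from_mapping(subclass: str, entry: dict) -> SubclassProfile:
    motifs = []
    for label, key in zip(("I", "II", "III", "IV"),
                          ("motif_I", "motif_II", "motif_III", "motif_IV")):
        if key not in entry:
            raise ValueError(f"profile {subclass!r} lacks {key}")
        spec = entry[key]
        motifs.append(
            parse_pattern(
                spec["pattern"], label=label,
                hallmark=spec.get("hallmark", ()),
            )
        )
    ranges = []
    for key in ("dbm_I_II", "dbm_II_III", "dbm_III_IV"):
        if key not in entry:
            raise ValueError(f"profile {subclass!r} lacks {key}")
        lo, hi = entry[key]
        ranges.append((int(lo), int(hi)))
    exceptions = tuple(
        (str(k), tuple(int(v) for v in vals))
        for k, vals in sorted(entry.get("dbm_exceptions", {}).items())
    )
    return SubclassProfile(
        subclass=subclass,
        motifs=tuple(motifs),
        dbm_ranges=tuple(ranges),
        dbm_exceptions=exceptions,
    )


def load_profiles(path: str | Path | None = None) -> dict[str, SubclassProfile]:
    """Load subclass profiles from YAML; shipped fixtures by default.

    The returned dict preserves the canonical subclass order for any
    subclass named in :data:`SUBCLASS_ORDER`; additional user-defined
    subclasses follow in file order.
    """
    if path is None:
        source = (
            importlib.resources.files("acylscan") / "data" / "profiles.yaml"
        )
        raw = yaml.safe_load(source.read_text(encoding="utf-8"))
    else:
        raw = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
    if not isinstance(raw, dict) or not raw:
        raise ValueError("profile file must map subclass names to entries")
    profiles = {
        name: _profile_from_mapping(name, entry) for name, entry in raw.items()
    }
    ordered: dict[str, SubclassProfile] = {}
    for name in SUBCLASS_ORDER:
        if name in profiles:
            ordered[name] = profiles.pop(name)
    ordered.update(profiles)
    return ordered
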