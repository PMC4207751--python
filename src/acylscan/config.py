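"""Run configuration: a flat, YAML-round-trippable set of knobs."""

from __future__ import annotations

import hashlib
from dataclasses import asdict, dataclass, fields
from pathlib import Path

import yaml


@dataclass
class RunConfig:
    """All tunables of an end-to-end synthetic run."""

    profiles_path: str | None = None  # None = shipped fixtures
    # classification
    min_margin: float = 2.0
    min_motifs: int = 4
    dbm_mode: str = "soft"
    dbm_convention: str = "strict"
    # alignment / survey
    matrix_name: str = "BLOSUM62"
    gap_open: int = 11
    gap_extend: int = 1
    lam: float = 0.267
    k: float = 0.041
    evalue_cutoff: float = 0.05
    reciprocal_cutoff: float = 10.0
    pssm_threshold: float = 0.5
    pseudocount: float = 0.5
    min_motif_evidence: int = 1
    # synthetic scenario
    scenario_preset: str = "default"
    n_per_proteome: int = 120
    divergence: float = 0.05
    background: str = "uniform"
    seed: int = 17
    # output
    out_dir: str = "acylscan_out"

    def __post_init__(self) -> None:
        for name in ("min_margin", "evalue_cutoff", "reciprocal_cutoff",
                     "pssm_threshold", "pseudocount", "lam", "k",
                     "divergence"):
            value = getattr(self, name)
            if not isinstance(value, (int, float)) or value != value:
                raise ValueError(f"{name} must be a finite number")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        if not isinstance(raw, dict):
            raise ValueError("config file must be a YAML mapping")
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(
                f"unknown config keys: {sorted(unknown)} "
                f"(known: {sorted(known)})"
            )
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(self.canonical_yaml(), encoding="utf-8")

    def canonical_yaml(self) -> str:
        return yaml.safe_dump(asdict(self), sort_keys=True)

    def digest(self) -> str:
        """Stable hash of the configuration, ignoring the output path."""
        payload = asdict(self)
        payload.pop("out_dir")
        return hashlib.sha256(
            yaml.safe_dump(payload, sort_keys=True).encode("utf-8")
        ).hexdigest()[:16]
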