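"""Assign proteins to acyltransferase subclasses from their motif chains.

Each protein is scanned against all six subclass profiles in soft-spacing
mode.  Full four-motif chains are required for a call (a three-motif
fallback yields a tentative ``partial`` call); the spacing of the
catalytic H/D dyad in motif I (HX5D for fungal microsomal GPATs, HX4D for
everything else) acts as a hard filter between the two deep branches; and
the winner must beat the runner-up by a configurable score margin.  When
the margin is inconclusive but all contenders belong to the
mitoGPAT/fGDPAT/DHAPAT branch — whose motifs are nearly identical — the
call is the branch label ``GDPAT-like``, deliberately refusing to assign
substrate preference.
"""

from __future__ import annotations

import logging
import math
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .profiles import HX5D_SUBCLASSES, SUBCLASS_ORDER, SubclassProfile
from .pts1 import PTS1Call, detect_pts1
from .scan import MotifChain, hx_spacing, scan_chain

logger = logging.getLogger(__name__)

#: the three subclasses that share near-identical motifs I-IV
GDPAT_BRANCH = frozenset({"mitoGPAT", "fGDPAT", "DHAPAT"})
GDPAT_LIKE = "GDPAT-like"

#: row order of presence/absence matrices
MATRIX_ROWS = SUBCLASS_ORDER + (GDPAT_LIKE,)


@dataclass(frozen=True)
class ClassificationResult:
    """Per-protein subclass call."""

    protein_id: str
    best_subclass: str | None
    status: str  # confident | partial | ambiguous | none
    scores: dict[str, float] = field(default_factory=dict)
    margin: float = 0.0
    hx_class: str | None = None  # HX4D | HX5D | None
    pts1: PTS1Call | None = None
    chain: MotifChain | None = None

    @property
    def is_call(self) -> bool:
        return self.best_subclass is not None


def _hx_class_of(seq: str, chain: MotifChain) -> str | None:
    if chain.placements[0] is None:
        return None
    try:
        spacing = hx_spacing(seq, chain)
    except ValueError:
        return None
    if spacing == 5:
        return "HX5D"
    if spacing == 4:
        return "HX4D"
    return None


def classify_sequence(
    seq: str,
    profiles: Mapping[str, SubclassProfile],
    min_motifs: int = 4,
    min_margin: float = 2.0,
    dbm_mode: str = "soft",
    protein_id: str = "query",
) -> ClassificationResult:
    """Classify one protein against a set of subclass profiles."""
    if not seq:
        raise ValueError(f"empty sequence for record {protein_id!r}")
    pts1 = detect_pts1(seq)

    status_if_called = "confident"
    candidates: dict[str, MotifChain] = {}
    for name, prof in profiles.items():
        chain = scan_chain(seq, prof, dbm_mode=dbm_mode, min_motifs=4)
        if chain is not None:
            candidates[name] = chain
    if not candidates and min_motifs <= 3:
        status_if_called = "partial"
        for name, prof in profiles.items():
            chain = scan_chain(seq, prof, dbm_mode=dbm_mode, min_motifs=3)
            if chain is not None:
                candidates[name] = chain

    if not candidates:
        return ClassificationResult(
            protein_id=protein_id, best_subclass=None, status="none",
            pts1=pts1,
        )

    scores = {name: chain.score for name, chain in candidates.items()}
    ranked = sorted(
        candidates,
        key=lambda name: (-scores[name], _subclass_rank(name)),
    )
    top = ranked[0]
    hx_class = _hx_class_of(seq, candidates[top])
    if hx_class is not None:
        wanted = hx_class == "HX5D"
        survivors = [
            name for name in ranked
            if (name in HX5D_SUBCLASSES) == wanted
        ]
    else:
        survivors = ranked

    best = survivors[0]
    runner_up = survivors[1] if len(survivors) > 1 else None
    margin = (
        scores[best] - scores[runner_up]
        if runner_up is not None else math.inf
    )
    if margin >= min_margin:
        call, status = best, status_if_called
    else:
        near = {
            name for name in survivors
            if scores[best] - scores[name] < min_margin
        }
        if near <= GDPAT_BRANCH:
            call, status = GDPAT_LIKE, status_if_called
        else:
            call, status = None, "ambiguous"
    return ClassificationResult(
        protein_id=protein_id,
        best_subclass=call,
        status=status,
        scores=scores,
        margin=margin,
        hx_class=hx_class,
        pts1=pts1,
        chain=candidates[best],
    )


def _subclass_rank(name: str) -> int:
    try:
        return SUBCLASS_ORDER.index(name)
    except ValueError:
        return len(SUBCLASS_ORDER)


def results_table(results: Sequence[ClassificationResult]) -> pd.DataFrame:
    """One row per protein; per-subclass chain scores as columns."""
    subclasses = sorted(
        {name for r in results for name in r.scores}, key=_subclass_rank
    )
    rows = []
    for r in results:
        row: dict[str, object] = {
            "id": r.protein_id,
            "best_subclass": r.best_subclass or ".",
            "status": r.status,
            "margin": round(r.margin, 4) if math.isfinite(r.margin) else "inf",
            "hx_class": r.hx_class or ".",
            "pts1_tier": r.pts1.tier if r.pts1 else "none",
            "pts1_tripeptide": r.pts1.tripeptide if r.pts1 else "",
        }
        for name in subclasses:
            row[f"score_{name}"] = (
                round(r.scores[name], 4) if name in r.scores else ""
            )
        rows.append(row)
    return pd.DataFrame(rows)


def write_results_tsv(
    results: Sequence[ClassificationResult], path: str | Path
) -> None:
    """Write the classification table with a commented header."""
    table = results_table(results)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("# acylscan classification report\n")
        fh.write("# coordinates: 0-based, half-open\n")
        table.to_csv(fh, sep="\t", index=False)


def classify_fasta(
    path: str | Path,
    profiles: Mapping[str, SubclassProfile],
    min_motifs: int = 4,
    min_margin: float = 2.0,
    dbm_mode: str = "soft",
    out_tsv: str | Path | None = None,
) -> list[ClassificationResult]:
    """Classify every record of a FASTA file, preserving input order."""
    from .io import read_fasta

    seqs = read_fasta(path)
    if not seqs:
        raise ValueError(f"no records in {path}")
    results = [
        classify_sequence(
            seq, profiles, min_motifs=min_motifs, min_margin=min_margin,
            dbm_mode=dbm_mode, protein_id=name,
        )
        for name, seq in seqs.items()
    ]
    counts = Counter(r.best_subclass or r.status for r in results)
    logger.info(
        "classified %d records: %s", len(results),
        ", ".join(f"{k}={v}" for k, v in sorted(counts.items())),
    )
    if out_tsv is not None:
        write_results_tsv(results, out_tsv)
    return results


def scan_report(
    seqs: Mapping[str, str],
    profiles: Mapping[str, SubclassProfile],
    dbm_mode: str = "soft",
) -> pd.DataFrame:
    """Per-protein, per-subclass chain placements (one row per profile
    tried that yielded a full chain)."""
    rows = []
    for seq_id, seq in seqs.items():
        for name, prof in profiles.items():
            chain = scan_chain(seq, prof, dbm_mode=dbm_mode)
            if chain is None or not chain.is_full:
                continue
            row: dict[str, object] = {"id": seq_id, "subclass": name}
            for k, label in enumerate(("I", "II", "III", "IV")):
                off, length = chain.placements[k]
                row[f"off_{label}"] = off
                row[f"len_{label}"] = length
            for k in range(3):
                row[f"dbm_{k + 1}"] = chain.dbm[k]
            row["score"] = round(chain.score, 4)
            row["mode"] = dbm_mode
            rows.append(row)
    return pd.DataFrame(rows)


def presence_absence(
    grouped: Mapping[str, Iterable[ClassificationResult]],
) -> pd.DataFrame:
    """Subclass x proteome boolean matrix from confident calls.

    A cell is true iff the proteome contains at least one confident call
    of that subclass (branch-level ``GDPAT-like`` calls occupy their own
    row and do not mark the three member subclasses).
    """
    columns = list(grouped)
    data = {col: [False] * len(MATRIX_ROWS) for col in columns}
    for col, results in grouped.items():
        for r in results:
            if r.status == "confident" and r.best_subclass in MATRIX_ROWS:
                data[col][MATRIX_ROWS.index(r.best_subclass)] = True
    return pd.DataFrame(data, index=list(MATRIX_ROWS), columns=columns)
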