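"""FASTA and report-file handling."""

from __future__ import annotations

from pathlib import Path
from typing import Mapping

import pandas as pd
from Bio import SeqIO


class FastaMap(dict):
    """Order-preserving id -> sequence map with record descriptions."""

    def __init__(self) -> None:
        super().__init__()
        self.descriptions: dict[str, str] = {}


def read_fasta(path: str | Path) -> FastaMap:
    """Read a protein FASTA file.

    Sequences are uppercased and a single terminal ``*`` stop symbol is
    stripped.  Duplicate identifiers and empty records raise ``ValueError``
    naming the offending record.
    """
    path = Path(path)
    result = FastaMap()
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in result:
            raise ValueError(f"duplicate record id {record.id!r} in {path}")
        seq = str(record.seq).upper()
        if seq.endswith("*"):
            seq = seq[:-1]
        if not seq:
            raise ValueError(f"empty record {record.id!r} in {path}")
        result[record.id] = seq
        result.descriptions[record.id] = record.description
    return result


def write_fasta(
    seqs: Mapping[str, str], path: str | Path, width: int = 60
) -> None:
    """Write an id -> sequence map as FASTA, 60 columns per line."""
    with open(path, "w", encoding="utf-8") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def write_matrix_tsv(
    matrix: pd.DataFrame, path: str | Path, comment: str = ""
) -> None:
    """Write a boolean presence/absence matrix as 0/1 TSV."""
    with open(path, "w", encoding="utf-8") as fh:
        if comment:
            for line in comment.splitlines():
                fh.write(f"# {line}\n")
        matrix.astype(int).to_csv(fh, sep="\t", index_label="subclass")


def read_matrix_tsv(path: str | Path) -> pd.DataFrame:
    """Inverse of :func:`write_matrix_tsv`."""
    frame = pd.read_csv(path, sep="\t", comment="#", index_col="subclass")
    return frame.astype(bool)
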