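#!/usr/bin/env python
"""Optional helper: download the seven published seed accessions.

Fetches the functionally characterised GPAT/DHAPAT seed proteins from
NCBI (network required) and writes them to a FASTA file whose record
ids are prefixed with the subclass they seed, ready for
``acylscan survey --seeds``.  The package and its test suite do not
depend on this script or on the downloaded file.

Usage:
    python scripts/fetch_seeds.py --email you@example.org --out seeds.fasta
"""

from __future__ import annotations

import argparse

from Bio import Entrez, SeqIO

#: accession -> (subclass, common name)
SEED_ACCESSIONS = {
    "NP_009542.1": ("fGPAT-A", "Sct1"),
    "NP_012993.1": ("fGPAT-A", "Gpt2"),
    "NP_065969.3": ("mitoGPAT", "GPAT1"),
    "NP_997211.2": ("mitoGPAT", "GPAT2"),
    "NP_055051.1": ("DHAPAT", "DHAPAT"),
    "NP_116106.2": ("eGPAT", "GPAT3"),
    "NP_848934.1": ("eGPAT", "GPAT4"),
}


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--email", required=True,
                        help="Contact email for NCBI Entrez.")
    parser.add_argument("--out", required=True)
    args = parser.parse_args()

    Entrez.email = args.email
    with open(args.out, "w", encoding="utf-8") as fh:
        for accession, (subclass, name) in SEED_ACCESSIONS.items():
            handle = Entrez.efetch(
                db="protein", id=accession, rettype="fasta",
                retmode="text",
            )
            record = SeqIO.read(handle, "fasta")
            handle.close()
            fh.write(f">{subclass}|{name}_{accession}\n")
            seq = str(record.seq)
            for i in range(0, len(seq), 60):
                fh.write(seq[i:i + 60] + "\n")
            print(f"fetched {accession} ({subclass} {name}, "
                  f"{len(record.seq)} aa)")


if __name__ == "__main__":
    main()
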