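"""File I/O for the formats the pipeline exchanges.

FASTA/FASTQ go through Biopython; tables are pandas TSV.  Everything is
plain text so fixtures and pipeline outputs stay diff-able.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from ._seq import Read

__all__ = [
    "read_fasta",
    "write_fasta",
    "read_fastq",
    "write_fastq",
    "read_taxonomy",
    "write_taxonomy",
    "read_profile_matrix",
    "write_profile_matrix",
]


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(genomes: Mapping[str, str], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in genomes.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def read_fastq(path: str | Path) -> list[Read]:
    reads = []
    for rec in SeqIO.parse(str(path), "fastq"):
        qual = "".join(chr(q + 33) for q in rec.letter_annotations["phred_quality"])
        reads.append(Read(rec.id, str(rec.seq).upper(), qual))
    return reads


def write_fastq(reads: Iterable[Read], path: str | Path) -> None:
    # Plain formatting keeps byte-identical reruns trivial to reason about.
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f"@{r.id}\n{r.sequence}\n+\n{r.quality}\n")


def read_taxonomy(path: str | Path) -> pd.DataFrame:
    tax = pd.read_csv(path, sep="\t", dtype=str)
    required = {"species_id", "genus", "phylum"}
    if not required <= set(tax.columns):
        raise ValueError(f"taxonomy table needs columns {sorted(required)}")
    return tax


def write_taxonomy(tax: pd.DataFrame, path: str | Path) -> None:
    tax.to_csv(path, sep="\t", index=False)


def read_profile_matrix(path: str | Path) -> pd.DataFrame:
    """Taxa x samples relative-abundance matrix."""
    return pd.read_csv(path, sep="\t", index_col=0)


def write_profile_matrix(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t")
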