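"""File-format helpers (FASTA/FASTQ via Biopython, GFF3/TSV via pandas).

GFF3 coordinates are 1-based inclusive on disk; everything internal is
0-based half-open.  Conversion happens only here.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Iterator

import pandas as pd
from Bio import SeqIO
from Bio.SeqIO.QualityIO import FastqGeneralIterator

GFF_COLUMNS = [
    "seqid", "source", "type", "start", "end",
    "score", "strand", "phase", "attributes",
]


def read_fasta(path: str | Path) -> dict[str, str]:
    """FASTA file -> {record id: uppercase sequence} (insertion-ordered)."""
    return {
        rec.id: str(rec.seq).upper()
        for rec in SeqIO.parse(str(path), "fasta")
    }


def write_fasta(path: str | Path, records: Iterable[tuple[str, str]]) -> None:
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n{seq}\n")


def iter_fastq(path: str | Path) -> Iterator[tuple[str, str, str]]:
    """Yield (title, sequence, quality) from a FASTQ file."""
    with open(path) as fh:
        yield from FastqGeneralIterator(fh)


def write_fastq(
    path: str | Path, records: Iterable[tuple[str, str, str]]
) -> None:
    with open(path, "w") as fh:
        for title, seq, qual in records:
            fh.write(f"@{title}\n{seq}\n+\n{qual}\n")


def read_gff(path: str | Path) -> pd.DataFrame:
    """Read a GFF3 file into a DataFrame (start/end kept 1-based as on disk)."""
    df = pd.read_csv(
        path, sep="\t", comment="#", header=None, names=GFF_COLUMNS,
        dtype={"seqid": str, "attributes": str},
    )
    return df


def write_gff(path: str | Path, rows: pd.DataFrame) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        rows.to_csv(fh, sep="\t", header=False, index=False)


def gff_attr(attributes: str, key: str) -> str | None:
    for part in attributes.split(";"):
        if "=" in part:
            k, v = part.split("=", 1)
            if k == key:
                return v
    return None


def read_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_tsv(path: str | Path, df: pd.DataFrame) -> None:
    df.to_csv(path, sep="\t", index=False)
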