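"""Thin FASTA/FASTQ ingestion and emission helpers (plain or gzipped).

Reading goes through Biopython's SeqIO; writing of simulated fixtures uses
direct text emission (constant-quality FASTQ at fixture scale).
"""

from __future__ import annotations

import gzip
from collections.abc import Iterable, Iterator
from pathlib import Path

from Bio import SeqIO

__all__ = ["read_sequences", "sniff_format", "write_fasta", "write_fastq"]


def _open_text(path: str | Path):
    if str(path).endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path, "rt")


def sniff_format(path: str | Path) -> str:
    """Guess 'fasta' or 'fastq' from the extension, else the first byte."""
    name = str(path)
    if name.endswith(".gz"):
        name = name[:-3]
    suffix = Path(name).suffix.lower()
    if suffix in {".fa", ".fasta", ".fna", ".ffn"}:
        return "fasta"
    if suffix in {".fq", ".fastq"}:
        return "fastq"
    with _open_text(path) as fh:
        first = fh.read(1)
    if first == ">":
        return "fasta"
    if first == "@":
        return "fastq"
    raise ValueError(f"cannot determine sequence format of {path}")


def read_sequences(path: str | Path, fmt: str | None = None) -> Iterator[str]:
    """Yield uppercase sequence strings from a FASTA/FASTQ file."""
    fmt = fmt or sniff_format(path)
    with _open_text(path) as fh:
        for record in SeqIO.parse(fh, fmt):
            yield str(record.seq).upper()


def write_fasta(records: Iterable[tuple[str, str]], path: str | Path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_fastq(records: Iterable[tuple[str, str]], path: str | Path, quality_char: str = "I") -> None:
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f"@{name}\n{seq}\n+\n{quality_char * len(seq)}\n")
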