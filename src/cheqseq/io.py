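"""Thin FASTA/FASTQ I/O helpers (Biopython-backed, gzip-aware)."""

from __future__ import annotations

import gzip
from dataclasses import dataclass
from typing import Iterable, Iterator

import numpy as np
from Bio import SeqIO


@dataclass(frozen=True)
class Read:
    """A sequencing read with per-base Phred qualities."""

    name: str
    sequence: str
    qualities: np.ndarray | None = None

    @property
    def mean_quality(self) -> float:
        if self.qualities is None or len(self.qualities) == 0:
            return float("nan")
        return float(np.mean(self.qualities))

    @property
    def min_quality(self) -> float:
        if self.qualities is None or len(self.qualities) == 0:
            return float("nan")
        return float(np.min(self.qualities))


def _open_text(path, mode="rt"):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


def read_fastq(path) -> Iterator[Read]:
    """Yield :class:`Read` objects from a (possibly gzipped) FASTQ file."""
    with _open_text(path) as fh:
        for rec in SeqIO.parse(fh, "fastq"):
            yield Read(
                name=rec.id,
                sequence=str(rec.seq),
                qualities=np.asarray(
                    rec.letter_annotations["phred_quality"], dtype=np.int16
                ),
            )


def write_fastq(reads: Iterable[Read], path) -> None:
    with _open_text(path, "wt") as fh:
        for r in reads:
            qual = "".join(chr(q + 33) for q in (r.qualities if r.qualities is not None else []))
            fh.write(f"@{r.name}\n{r.sequence}\n+\n{qual}\n")


def read_fasta(path) -> Iterator[tuple[str, str]]:
    with _open_text(path) as fh:
        for rec in SeqIO.parse(fh, "fasta"):
            yield rec.id, str(rec.seq)


def write_fasta(records: Iterable[tuple[str, str]], path, width: int = 80) -> None:
    with _open_text(path, "wt") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")
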