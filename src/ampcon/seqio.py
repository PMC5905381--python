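"""Sequence I/O: strict 4-line FASTQ (phred+33) in, 80-column FASTA out.

Reads are uppercased on input and validated against the {A,C,G,T,N}
alphabet.  Gzip-compressed FASTQ/FASTA inputs are accepted by ``.gz``
extension.  Quality averaging uses the error-probability scale, the
convention of nanopore read-filtering tools: a read full of Q10 bases and a
single Q30 base is barely better than Q10, not Q20.
"""

from __future__ import annotations

import gzip
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence, TextIO

import numpy as np

_VALID = set("ACGTN")

OFFSET = 33  # phred+33


class FastqParseError(ValueError):
    """Malformed FASTQ record; message names the offending line number."""


@dataclass
class Read:
    """One sequencing read: id, nucleotide sequence, per-base phred scores."""

    id: str
    seq: str
    qual: list[int] = field(repr=False)

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("read id must be nonempty")
        if len(self.qual) != len(self.seq):
            raise ValueError(
                f"read {self.id!r}: qual length {len(self.qual)} != "
                f"seq length {len(self.seq)}"
            )

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class SeqRecord:
    """A named nucleotide sequence without quality (references, consensi)."""

    id: str
    seq: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("record id must be nonempty")

    def __len__(self) -> int:
        return len(self.seq)


def _open_text(path: str | Path, mode: str = "rt") -> TextIO:
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)  # type: ignore[return-value]
    return open(path, mode)


def _check_seq(seq: str, lineno: int) -> str:
    seq = seq.upper()
    bad = set(seq) - _VALID
    if bad:
        raise FastqParseError(
            f"line {lineno}: invalid sequence character(s) {sorted(bad)}"
        )
    return seq


def read_fastq(path: str | Path) -> Iterator[Read]:
    """Yield :class:`Read` objects from a 4-line phred+33 FASTQ file."""
    with _open_text(path) as fh:
        lineno = 0
        while True:
            header = fh.readline()
            if not header:
                return
            lineno += 1
            header = header.rstrip("\n")
            if not header.startswith("@"):
                raise FastqParseError(f"line {lineno}: expected '@', got {header[:20]!r}")
            rid = header[1:].split()[0] if header[1:].strip() else ""
            if not rid:
                raise FastqParseError(f"line {lineno}: empty read id")
            seq = fh.readline()
            if not seq:
                raise FastqParseError(f"line {lineno + 1}: truncated record (missing sequence)")
            lineno += 1
            seq = _check_seq(seq.rstrip("\n"), lineno)
            plus = fh.readline()
            if not plus or not plus.startswith("+"):
                raise FastqParseError(f"line {lineno + 1}: expected '+' separator")
            lineno += 1
            qline = fh.readline()
            if not qline and seq:
                raise FastqParseError(f"line {lineno + 1}: truncated record (missing quality)")
            lineno += 1
            qline = qline.rstrip("\n")
            if len(qline) != len(seq):
                raise FastqParseError(
                    f"line {lineno}: quality length {len(qline)} != sequence length {len(seq)}"
                )
            qual = [ord(c) - OFFSET for c in qline]
            if any(q < 0 for q in qual):
                raise FastqParseError(f"line {lineno}: quality character below '!' (phred+33)")
            yield Read(id=rid, seq=seq, qual=qual)


def write_fastq(reads: Iterable[Read], path: str | Path) -> int:
    """Write reads as 4-line phred+33 FASTQ; returns the record count."""
    n = 0
    with _open_text(path, "wt") as fh:
        for r in reads:
            qline = "".join(chr(min(q, 93) + OFFSET) for q in r.qual)
            fh.write(f"@{r.id}\n{r.seq}\n+\n{qline}\n")
            n += 1
    return n


def read_fasta(path: str | Path) -> list[SeqRecord]:
    """Read a FASTA file into :class:`SeqRecord` objects (uppercased)."""
    records: list[SeqRecord] = []
    rid: str | None = None
    chunks: list[str] = []
    with _open_text(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith(">"):
                if rid is not None:
                    records.append(SeqRecord(rid, "".join(chunks)))
                rid = line[1:].split()[0]
                chunks = []
            elif line:
                chunks.append(line.upper())
        if rid is not None:
            records.append(SeqRecord(rid, "".join(chunks)))
    return records


def write_fasta(records: Sequence[SeqRecord], path: str | Path, wrap: int = 80) -> None:
    """Write records as FASTA, 80-column wrapped; ids must be unique."""
    ids = [r.id for r in records]
    dupes = {i for i in ids if ids.count(i) > 1}
    if dupes:
        raise ValueError(f"duplicate record id(s): {sorted(dupes)}")
    with _open_text(path, "wt") as fh:
        for r in records:
            fh.write(f">{r.id}\n")
            for i in range(0, len(r.seq), wrap):
                fh.write(r.seq[i : i + wrap] + "\n")


def mean_quality(read: Read) -> float:
    """Error-rate-averaged phred quality: −10·log10(mean 10^(−q/10)).

    This is the per-read score thresholded by the quality filter; it is
    dominated by the worst bases, unlike an arithmetic mean of phred values.
    """
    if not read.qual:
        raise ValueError(f"read {read.id!r}: empty quality string")
    q = np.asarray(read.qual, dtype=float)
    return float(-10.0 * math.log10(np.mean(10.0 ** (-q / 10.0))))
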