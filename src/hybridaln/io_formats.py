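"""Sequence file readers and writers.

FASTA and FASTQ parsing is delegated to Biopython's SeqIO; gzip compression
is auto-detected from the two magic bytes so ``.fa`` and ``.fa.gz`` are
interchangeable everywhere a path is accepted.  CSFASTA (SOLiD color-space
records: one primer base followed by digits ``0-3`` and ``.`` for missing
colors) has no parser in the installed stack and is read here directly.
"""

from __future__ import annotations

import gzip
import io
import os
from dataclasses import dataclass
from typing import Iterator, Optional, TextIO

from Bio import SeqIO

GZIP_MAGIC = b"\x1f\x8b"


@dataclass
class SeqRecord:
    """A minimal (id, sequence, optional quality) record."""

    id: str
    sequence: str
    quality: Optional[str] = None


class FormatError(ValueError):
    """Raised for malformed or truncated input files."""


def _is_gzip(path: str | os.PathLike) -> bool:
    with open(path, "rb") as fh:
        return fh.read(2) == GZIP_MAGIC


def open_text(path: str | os.PathLike) -> TextIO:
    """Open a possibly gzip-compressed text file for reading."""
    if _is_gzip(path):
        return io.TextIOWrapper(gzip.open(path, "rb"), newline=None)
    return open(path, "rt", newline=None)


def sniff_format(path: str | os.PathLike) -> str:
    """Return 'fasta', 'fastq' or 'csfasta' from the first meaningful byte."""
    with open_text(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                continue  # CSFASTA comment header
            if line.startswith("@"):
                return "fastq"
            if line.startswith(">"):
                # CSFASTA records carry a leading primer base then digits
                seq = next((l.strip() for l in fh if l.strip()), "")
                if seq and seq[0].upper() in "ACGT" and all(
                    c in "0123." for c in seq[1:]
                ):
                    return "csfasta"
                return "fasta"
            raise FormatError(f"{path}: cannot determine sequence format")
    return "fasta"  # empty file: let the consumer report what's missing


def read_sequences(path: str | os.PathLike) -> Iterator[SeqRecord]:
    """Stream records from FASTA/FASTQ/CSFASTA, plain or gzipped.

    FASTQ records yield their quality string; FASTA records yield
    ``quality=None``.  Truncated FASTQ records raise :class:`FormatError`
    naming the offending line.
    """
    fmt = sniff_format(path)
    if fmt == "csfasta":
        yield from read_csfasta(path)
        return
    with open_text(path) as fh:
        if fmt == "fastq":
            yield from _read_fastq(fh, str(path))
        else:
            for rec in SeqIO.parse(fh, "fasta"):
                yield SeqRecord(rec.id, str(rec.seq).upper())


def _read_fastq(fh: TextIO, name: str) -> Iterator[SeqRecord]:
    lineno = 0
    while True:
        lines = []
        for _ in range(4):
            line = fh.readline()
            lineno += 1
            if line == "":
                if not lines or all(not l.strip() for l in lines):
                    return
                raise FormatError(
                    f"{name}: truncated FASTQ record at line {lineno}"
                )
            lines.append(line.rstrip("\r\n"))
        head, seq, plus, qual = lines
        if not head.startswith("@") or not plus.startswith("+"):
            raise FormatError(f"{name}: malformed FASTQ record at line {lineno - 3}")
        if len(seq) != len(qual):
            raise FormatError(
                f"{name}: sequence/quality length mismatch at line {lineno - 3}"
            )
        yield SeqRecord(head[1:].split()[0], seq.upper(), qual)


def read_csfasta(
    path: str | os.PathLike, qual_path: str | os.PathLike | None = None
) -> Iterator[SeqRecord]:
    """Read SOLiD CSFASTA records (primer base + color digits).

    If *qual_path* is given, per-color PHRED values are read in parallel and
    attached as a PHRED+33 string.
    """
    quals = {}
    if qual_path is not None:
        with open_text(qual_path) as qh:
            qid = None
            for line in qh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                if line.startswith(">"):
                    qid = line[1:].split()[0]
                else:
                    vals = [int(v) for v in line.split()]
                    quals[qid] = "".join(chr(min(v, 60) + 33) for v in vals)
    with open_text(path) as fh:
        rid = None
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if line.startswith(">"):
                rid = line[1:].split()[0]
            else:
                if rid is None:
                    raise FormatError(f"{path}: color line before record header")
                if line[0].upper() not in "ACGT":
                    raise FormatError(
                        f"{path}: record {rid} lacks a primer base"
                    )
                yield SeqRecord(rid, line.upper(), quals.get(rid))
                rid = None


def _normalize_pair_id(rid: str) -> str:
    if len(rid) > 2 and rid[-2] == "/" and rid[-1] in "12":
        return rid[:-2]
    return rid


def read_paired(
    path1: str | os.PathLike, path2: str | os.PathLike
) -> Iterator[tuple[SeqRecord, SeqRecord]]:
    """Yield synchronized read pairs from two files.

    IDs with ``/1`` and ``/2`` suffixes are normalized to the shared stem.
    A record-count mismatch raises :class:`FormatError` at the first
    divergence.
    """
    it1, it2 = read_sequences(path1), read_sequences(path2)
    n = 0
    while True:
        r1 = next(it1, None)
        r2 = next(it2, None)
        if r1 is None and r2 is None:
            return
        if r1 is None or r2 is None:
            short = path1 if r1 is None else path2
            raise FormatError(f"{short}: ran out of records after {n} pairs")
        r1.id = _normalize_pair_id(r1.id)
        r2.id = _normalize_pair_id(r2.id)
        n += 1
        yield r1, r2


def write_fasta(path: str | os.PathLike, records) -> None:
    with open(path, "wt") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            seq = rec.sequence
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")


def write_fastq(path: str | os.PathLike, records) -> None:
    with open(path, "wt") as fh:
        for rec in records:
            q = rec.quality or "I" * len(rec.sequence)
            fh.write(f"@{rec.id}\n{rec.sequence}\n+\n{q}\n")


def write_csfasta(path: str | os.PathLike, records) -> None:
    with open(path, "wt") as fh:
        fh.write("# hybridaln CSFASTA\n")
        for rec in records:
            fh.write(f">{rec.id}\n{rec.sequence}\n")
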