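"""Synthetic data generation and alignment-quality evaluation.

The simulator emulates the benchmark conditions used throughout the tool's
evaluation: uniform-random genomes, Illumina-like 100-bp read pairs with
per-base substitution errors and insert sizes drawn from N(mean, sd) in FR
orientation, and SOLiD-like color-space mate pairs (FF orientation,
per-color errors).  Ground truth (contig, leftmost position, strand) is
recorded per end before errors are injected.

The evaluator computes the quality metrics used to benchmark aligners:

* sensitivity — aligned reads / total reads (percent);
* recall (all) — reads with *any* reported alignment within 10 bp of the
  true position, same contig and strand / total reads;
* recall (first) — same, restricted to the first alignment occurrence per
  read in the SAM file;
* a MAPQ-ordered ROC: for each threshold q, TPR = correctly aligned reads
  with MAPQ >= q / total reads, FPR = incorrectly aligned reads with
  MAPQ >= q / aligned reads with MAPQ >= q.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, field
from typing import Optional, Union

import numpy as np
import pandas as pd
import pysam

from .colorspace import encode_colors
from .index import revcomp
from .io_formats import SeqRecord

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class SimulatedRead:
    """A simulated read plus the error-free source locus."""

    read_id: str
    sequence: str
    quality: str
    true_contig: str
    true_pos: int  # 0-based leftmost on the forward reference
    true_strand: str
    pair_id: str = ""
    end_index: int = 1


@dataclass
class EvalReport:
    sensitivity: float
    recall_all: float
    recall_first: float
    roc: list  # [(mapq, TPR, FPR)] in percent
    n_reads: int
    n_aligned: int
    mode: str = "all"

    @property
    def recall(self) -> float:
        return self.recall_all if self.mode == "all" else self.recall_first

    def summary(self) -> dict:
        return {
            "n_reads": self.n_reads,
            "n_aligned": self.n_aligned,
            "sensitivity": round(self.sensitivity, 2),
            "recall_all": round(self.recall_all, 2),
            "recall_first": round(self.recall_first, 2),
        }


def simulate_genome(
    length: int,
    gc: float = 0.5,
    seed: int = 0,
    n_contigs: int = 1,
    name_prefix: str = "sim",
) -> list[SeqRecord]:
    """I.i.d. random genome at the given GC fraction, deterministic per seed."""
    if length < 1:
        raise ValueError("length must be positive")
    if not 0.0 <= gc <= 1.0:
        raise ValueError("gc must be in [0, 1]")
    rng = np.random.default_rng(seed)
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    per = length // n_contigs
    records = []
    for i in range(n_contigs):
        n = per if i < n_contigs - 1 else length - per * (n_contigs - 1)
        codes = rng.choice(4, size=n, p=p)
        records.append(
            SeqRecord(f"{name_prefix}{i + 1}", _BASES[codes].tobytes().decode())
        )
    return records


def _contig_list(genome) -> list[tuple[str, str]]:
    if isinstance(genome, (str, os.PathLike)):
        from .io_formats import read_sequences

        return [(r.id, r.sequence) for r in read_sequences(genome)]
    return [(r.id, r.sequence) for r in genome]


def _mutate(seq: str, err_rate: float, rng) -> str:
    if err_rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    hits = np.nonzero(rng.random(arr.size) < err_rate)[0]
    for i in hits:
        choices = _BASES[_BASES != arr[i]]
        arr[i] = choices[rng.integers(len(choices))]
    return arr.tobytes().decode()


def _phred_char(err_rate: float) -> str:
    q = int(round(-10 * math.log10(max(err_rate, 1e-4))))
    return chr(min(q, 60) + 33)


def simulate_pe_reads(
    genome,
    n_pairs: int,
    read_len: int = 100,
    err_rate: float = 0.02,
    insert_mean: float = 500.0,
    insert_sd: float = 50.0,
    seed: int = 0,
    id_prefix: str = "r",
    indel_rate: float = 0.0,
    indel_len: int = 12,
) -> tuple[list[tuple[SimulatedRead, SimulatedRead]], pd.DataFrame]:
    """Illumina-like FR read pairs with substitution errors.

    Loci are uniform over the genome; the fragment strand is random; truth
    is recorded per end before errors.  With ``indel_rate`` > 0 a read may
    additionally carry one ``indel_len``-bp deletion relative to the
    genome (for exercising the semi-global rescue path).
    """
    if insert_mean < 2 * read_len:
        raise ValueError("insert_mean must be >= 2 * read_len")
    contigs = _contig_list(genome)
    usable = [(n, s) for n, s in contigs if len(s) >= insert_mean + 6 * insert_sd]
    if not usable:
        raise ValueError("genome too short for the requested insert size")
    rng = np.random.default_rng(seed)
    weights = np.array([len(s) for _, s in usable], dtype=float)
    weights /= weights.sum()
    qual = _phred_char(err_rate) * read_len
    pairs = []
    rows = []

    def _make_end(cseq: str, pos: int, strand: str) -> tuple[str, int]:
        """Read bases drawn at `pos` (leftmost, forward coords)."""
        src_len = read_len
        if indel_rate > 0 and rng.random() < indel_rate:
            src_len = read_len + indel_len
        frag = cseq[pos : pos + src_len]
        if src_len > read_len:  # one internal deletion in the read
            cut = int(rng.integers(10, read_len - 10))
            frag = frag[:cut] + frag[cut + indel_len :]
        bases = frag if strand == "+" else revcomp(frag)
        return _mutate(bases, err_rate, rng), pos

    for i in range(n_pairs):
        ci = int(rng.choice(len(usable), p=weights))
        cname, cseq = usable[ci]
        ins = int(round(rng.normal(insert_mean, insert_sd)))
        ins = max(read_len, min(ins, len(cseq)))
        p = int(rng.integers(0, len(cseq) - ins + 1))
        frag_fwd = rng.random() < 0.5
        pid = f"{id_prefix}{i}"
        # FR layout: forward end at fragment start, reverse end at its tail
        left = (p, "+")
        right = (p + ins - read_len, "-")
        (p1, s1), (p2, s2) = (left, right) if frag_fwd else (right, left)
        seq1, _ = _make_end(cseq, p1, s1)
        seq2, _ = _make_end(cseq, p2, s2)
        r1 = SimulatedRead(f"{pid}/1", seq1, qual, cname, p1, s1, pid, 1)
        r2 = SimulatedRead(f"{pid}/2", seq2, qual, cname, p2, s2, pid, 2)
        pairs.append((r1, r2))
        rows.append((r1.read_id, cname, p1, s1))
        rows.append((r2.read_id, cname, p2, s2))
    truth = pd.DataFrame(rows, columns=["read_id", "contig", "pos", "strand"])
    return pairs, truth


def simulate_color_pairs(
    genome,
    n_pairs: int,
    read_len: int = 50,
    err_rate: float = 0.02,
    insert_mean: float = 200.0,
    insert_sd: float = 20.0,
    seed: int = 0,
    id_prefix: str = "c",
    primer: str = "T",
) -> tuple[list[tuple[SimulatedRead, SimulatedRead]], pd.DataFrame]:
    """SOLiD-like mate pairs in FF orientation.

    Each record's sequence is CSFASTA-style: the primer base followed by
    ``read_len`` colors (the first color encodes the primer-to-first-base
    transition).  Color-level substitution errors are injected at
    ``err_rate``; truth refers to the error-free base-space locus.
    """
    if insert_mean < 2 * read_len:
        raise ValueError("insert_mean must be >= 2 * read_len")
    contigs = _contig_list(genome)
    usable = [(n, s) for n, s in contigs if len(s) >= insert_mean + 6 * insert_sd]
    if not usable:
        raise ValueError("genome too short for the requested insert size")
    rng = np.random.default_rng(seed)
    weights = np.array([len(s) for _, s in usable], dtype=float)
    weights /= weights.sum()
    qual = _phred_char(err_rate) * read_len

    def _colorize(bases: str) -> str:
        colors = encode_colors(primer + bases)
        if err_rate > 0:
            arr = list(colors)
            for j in np.nonzero(rng.random(len(arr)) < err_rate)[0]:
                if arr[j] == ".":
                    continue
                others = [c for c in "0123" if c != arr[j]]
                arr[j] = others[int(rng.integers(3))]
            colors = "".join(arr)
        return primer + colors

    pairs = []
    rows = []
    for i in range(n_pairs):
        ci = int(rng.choice(len(usable), p=weights))
        cname, cseq = usable[ci]
        ins = int(round(rng.normal(insert_mean, insert_sd)))
        ins = max(read_len, min(ins, len(cseq)))
        p = int(rng.integers(0, len(cseq) - ins + 1))
        frag_fwd = rng.random() < 0.5
        pid = f"{id_prefix}{i}"
        if frag_fwd:  # both ends forward (FF)
            b1, p1 = cseq[p : p + read_len], p
            b2, p2 = cseq[p + ins - read_len : p + ins], p + ins - read_len
            s1 = s2 = "+"
        else:  # both ends reverse
            b1, p1 = revcomp(cseq[p + ins - read_len : p + ins]), p + ins - read_len
            b2, p2 = revcomp(cseq[p : p + read_len]), p
            s1 = s2 = "-"
        r1 = SimulatedRead(f"{pid}/1", _colorize(b1), qual, cname, p1, s1, pid, 1)
        r2 = SimulatedRead(f"{pid}/2", _colorize(b2), qual, cname, p2, s2, pid, 2)
        pairs.append((r1, r2))
        rows.append((r1.read_id, cname, p1, s1))
        rows.append((r2.read_id, cname, p2, s2))
    truth = pd.DataFrame(rows, columns=["read_id", "contig", "pos", "strand"])
    return pairs, truth


def write_truth(path, truth: pd.DataFrame) -> None:
    truth.to_csv(path, sep="\t", index=False)


def read_truth(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"read_id": str, "contig": str})


class TruthMismatchError(KeyError):
    """A SAM read is absent from the truth table (mismatched runs)."""


def evaluate(
    sam: Union[str, os.PathLike],
    truth: Union[pd.DataFrame, str, os.PathLike],
    distance_tol: int = 10,
    min_mapq: int = 0,
    mode: str = "all",
) -> EvalReport:
    """Score a SAM file against simulation truth.

    An alignment is correct when it lands on the true contig and strand
    with leftmost-position distance <= ``distance_tol``.  Only alignments
    with MAPQ >= ``min_mapq`` are considered.  The denominator is the
    number of distinct reads present in the SAM (aligned or not), which
    must all be present in the truth table.
    """
    if not isinstance(truth, pd.DataFrame):
        truth = read_truth(truth)
    tmap = {
        r.read_id: (r.contig, int(r.pos), r.strand)
        for r in truth.itertuples(index=False)
    }
    per_read: dict = {}
    with pysam.AlignmentFile(str(sam), "r", check_sq=False) as fh:
        for rec in fh:
            key = rec.query_name
            if rec.is_paired:
                key = f"{key}/{'1' if rec.is_read1 else '2'}"
            if key not in tmap:
                raise TruthMismatchError(
                    f"read {key!r} in SAM but not in the truth table"
                )
            entry = per_read.setdefault(key, [])
            if rec.is_unmapped or rec.mapping_quality < min_mapq:
                continue
            tc, tp, ts = tmap[key]
            correct = (
                rec.reference_name == tc
                and ("-" if rec.is_reverse else "+") == ts
                and abs(rec.reference_start - tp) <= distance_tol
            )
            entry.append((int(rec.mapping_quality), bool(correct)))
    n_reads = len(per_read)
    if n_reads == 0:
        raise ValueError("SAM contains no reads")
    n_aligned = sum(1 for alns in per_read.values() if alns)
    n_correct_all = sum(
        1 for alns in per_read.values() if any(c for _, c in alns)
    )
    n_correct_first = sum(1 for alns in per_read.values() if alns and alns[0][1])
    roc = []
    qvals = sorted(
        {q for alns in per_read.values() for q, _ in alns if q >= max(min_mapq, 1)},
        reverse=True,
    )
    for q in qvals:
        alnd = corr = 0
        for alns in per_read.values():
            over = [c for m, c in alns if m >= q]
            if over:
                alnd += 1
                if any(over):
                    corr += 1
        tpr = 100.0 * corr / n_reads
        fpr = 100.0 * (alnd - corr) / alnd if alnd else 0.0
        roc.append((q, tpr, fpr))
    return EvalReport(
        sensitivity=100.0 * n_aligned / n_reads,
        recall_all=100.0 * n_correct_all / n_reads,
        recall_first=100.0 * n_correct_first / n_reads,
        roc=roc,
        n_reads=n_reads,
        n_aligned=n_aligned,
        mode=mode,
    )
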