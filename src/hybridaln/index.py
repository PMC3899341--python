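"""Reference genome index: BWT/FM-index with a sampled suffix array.

The index supports exact backward search, occurrence location, and the two
exact seed types of the hybrid-seeding pipeline: maximal exact matches
(MEMs) and non-overlapping exact-match k-mers.  Contigs are concatenated
with single ``N`` separators so no match interval can straddle a contig
boundary (seed patterns never contain ``N``).

Alphabet codes: ``$``=0 (sentinel), A=1, C=2, G=3, T=4, N=5.  ``N`` is
excluded from the searchable alphabet: a pattern containing it matches
nothing.

The suffix array is built by numpy prefix doubling; the per-read hot loops
(backward search, LF-walk locate, seed enumeration) are numba kernels.
"""

from __future__ import annotations

import json
import math
import os
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from numba import njit

from .io_formats import read_sequences

_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate("$ACGTN"):
    _CODE[ord(_b)] = _i
# IUPAC ambiguity codes degrade to N (unsearchable)
for _b in "RYSWKMBDHVU":
    _CODE[ord(_b)] = 5

_DECODE = np.frombuffer(b"$ACGTN", dtype=np.uint8)

_COMP = str.maketrans("ACGTN", "TGCAN")

OCC_BLOCK = 64  # rank checkpoint spacing

SEED_MEM = "MEM"
SEED_KMER = "KMER"
SEED_VARLEN = "VARLEN"

INDEX_FORMAT_VERSION = 1


def revcomp(seq: str) -> str:
    """Reverse complement of a nucleotide string (N-safe)."""
    return seq.translate(_COMP)[::-1]


class InputError(ValueError):
    """Raised for invalid reference or read input."""


@dataclass
class Seed:
    """A read-to-genome anchor.

    ``read_offset`` is 0-based in the *oriented* read (the read itself on
    the forward strand, its reverse complement on the reverse strand);
    ``genome_pos`` is a 0-based global offset into the concatenated
    reference text.  ``score_q`` is the optimal local alignment score of
    the read against the mapping region derived from this seed; it is
    -inf until the ranking stage fills it in.
    """

    read_offset: int
    genome_pos: int
    length: int
    strand: str  # '+' | '-'
    kind: str = SEED_MEM
    score_q: float = float("-inf")
    region: Optional[object] = None  # MappingRegion, attached at ranking


def encode_seq(seq: str) -> np.ndarray:
    codes = _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    if (codes == 255).any():
        bad = seq[int(np.argmax(codes == 255))]
        raise InputError(f"non-IUPAC character {bad!r} in sequence")
    return codes


def decode_seq(codes: np.ndarray) -> str:
    return _DECODE[codes].tobytes().decode("ascii")


def build_suffix_array(codes: np.ndarray) -> np.ndarray:
    """Suffix array of a small-alphabet integer sequence via prefix doubling."""
    n = codes.size
    rank = codes.astype(np.int64)
    k = 1
    while True:
        key2 = np.full(n, -1, dtype=np.int64)
        key2[: n - k] = rank[k:]
        sa = np.lexsort((key2, rank))
        new = np.empty(n, dtype=np.int64)
        new[sa[0]] = 0
        diff = (rank[sa[1:]] != rank[sa[:-1]]) | (key2[sa[1:]] != key2[sa[:-1]])
        new[sa[1:]] = np.cumsum(diff)
        rank = new
        if rank[sa[-1]] == n - 1:
            return sa
        k *= 2


# ---------------------------------------------------------------------------
# numba kernels


@njit(cache=True, inline="always")
def _occ(bwt, ck, c, i):
    """Occurrences of code c in bwt[:i]."""
    blk = i >> 6
    cnt = ck[c, blk]
    for j in range(blk << 6, i):
        if bwt[j] == c:
            cnt += 1
    return cnt


@njit(cache=True)
def _backward_search(bwt, ck, cbase, pat):
    lo = np.int64(0)
    hi = np.int64(bwt.shape[0])
    for t in range(pat.shape[0] - 1, -1, -1):
        c = pat[t]
        if c < 1 or c > 4:
            return np.int64(0), np.int64(0)
        lo = cbase[c] + _occ(bwt, ck, c, lo)
        hi = cbase[c] + _occ(bwt, ck, c, hi)
        if lo >= hi:
            return np.int64(0), np.int64(0)
    return lo, hi


@njit(cache=True)
def _locate_row(bwt, ck, cbase, mark, markrank, vals, row):
    steps = 0
    r = row
    while not mark[r]:
        c = bwt[r]
        r = cbase[c] + _occ(bwt, ck, c, r)
        steps += 1
    return vals[markrank[r]] + steps


@njit(cache=True)
def _lf_walk_text(bwt, ck, cbase, row, count):
    """Walk LF from `row` `count` times, returning visited BWT symbols."""
    out = np.empty(count, dtype=np.uint8)
    r = row
    for i in range(count):
        c = bwt[r]
        out[i] = c
        r = cbase[c] + _occ(bwt, ck, c, r)
    return out


@njit(cache=True)
def _collect_exact_seeds(
    bwt, ck, cbase, mark, markrank, vals, rcodes,
    win_len, stride, max_occ, text, do_extend, out,
):
    """Enumerate exact seed candidates for one oriented read.

    Windows of `win_len` at offsets 0, stride, 2*stride, ... are searched
    exactly; each located occurrence is optionally extended to its maximal
    exact match on the text.  Rows beyond `max_occ` per window are dropped
    (first `max_occ` in suffix-array order).  Results (read_start,
    genome_start, length) are appended to `out`; returns the fill count.
    """
    L = rcodes.shape[0]
    n_out = 0
    cap = out.shape[0]
    i = 0
    while i + win_len <= L:
        ok = True
        for j in range(i, i + win_len):
            if rcodes[j] < 1 or rcodes[j] > 4:
                ok = False
                break
        if ok:
            lo, hi = _backward_search(bwt, ck, cbase, rcodes[i : i + win_len])
            nhit = hi - lo
            if nhit > max_occ:
                nhit = max_occ
            for h in range(nhit):
                p = _locate_row(bwt, ck, cbase, mark, markrank, vals, lo + h)
                rs = i
                gs = p
                ln = win_len
                if do_extend:
                    while (
                        rs > 0
                        and gs > 0
                        and rcodes[rs - 1] == text[gs - 1]
                        and rcodes[rs - 1] >= 1
                        and rcodes[rs - 1] <= 4
                    ):
                        rs -= 1
                        gs -= 1
                        ln += 1
                    while (
                        rs + ln < L
                        and gs + ln < text.shape[0]
                        and rcodes[rs + ln] == text[gs + ln]
                        and rcodes[rs + ln] >= 1
                        and rcodes[rs + ln] <= 4
                    ):
                        ln += 1
                dup = False
                for e in range(n_out):
                    if out[e, 0] == rs and out[e, 1] == gs and out[e, 2] == ln:
                        dup = True
                        break
                if not dup:
                    if n_out >= cap:
                        return n_out
                    out[n_out, 0] = rs
                    out[n_out, 1] = gs
                    out[n_out, 2] = ln
                    n_out += 1
        i += stride
    return n_out


# ---------------------------------------------------------------------------


@dataclass
class ReferenceIndex:
    """FM-index over the concatenated reference (plus sampled suffix array)."""

    names: list
    lengths: np.ndarray  # per-contig lengths
    starts: np.ndarray  # per-contig global start offsets
    text: np.ndarray  # concatenated codes incl. N separators (no sentinel)
    bwt: np.ndarray
    occ_ck: np.ndarray  # (6, nblocks+1) checkpointed ranks
    cbase: np.ndarray  # C array: #symbols < c
    sa_mark: np.ndarray  # bool: SA[row] % rate == 0
    sa_markrank: np.ndarray  # inclusive-cumsum - 1 over sa_mark
    sa_vals: np.ndarray  # SA values at marked rows
    sa_sample_rate: int = 8
    colorspace: bool = False

    # -- construction -------------------------------------------------

    @classmethod
    def from_records(
        cls, records, sa_sample_rate: int = 8, colorspace: bool = False
    ) -> "ReferenceIndex":
        names, seqs = [], []
        for rec in records:
            rid, seq = (rec.id, rec.sequence) if hasattr(rec, "id") else rec
            if not seq:
                raise InputError(f"contig {rid!r} is empty")
            names.append(rid)
            try:
                seqs.append(encode_seq(seq.upper()))
            except InputError as e:
                raise InputError(f"contig {rid!r}: {e}") from None
        if not names:
            raise InputError("reference contains no contigs")
        if sa_sample_rate < 1:
            raise InputError("sa_sample_rate must be a positive integer")
        lengths = np.array([s.size for s in seqs], dtype=np.int64)
        starts = np.zeros(len(seqs), dtype=np.int64)
        parts = []
        pos = 0
        sep = np.array([5], dtype=np.uint8)  # N separator
        for i, s in enumerate(seqs):
            starts[i] = pos
            parts.append(s)
            pos += s.size
            if i + 1 < len(seqs):
                parts.append(sep)
                pos += 1
        text = np.concatenate(parts) if len(parts) > 1 else parts[0]
        s = np.concatenate([text, np.array([0], dtype=np.uint8)])
        sa = build_suffix_array(s)
        n = s.size
        bwt = np.where(sa == 0, s[-1], s[(sa - 1) % n]).astype(np.uint8)
        # checkpointed ranks
        nblk = (n >> 6) + 1
        occ_ck = np.zeros((6, nblk + 1), dtype=np.int64)
        for c in range(6):
            hits = (bwt == c)
            csum = np.cumsum(hits)
            # occ_ck[c, b] = occurrences of c in bwt[: b*64]
            idx = np.minimum(np.arange(nblk + 1) * OCC_BLOCK, n)
            occ_ck[c] = np.where(idx > 0, csum[np.maximum(idx - 1, 0)], 0)
            occ_ck[c, 0] = 0
        counts = np.bincount(s, minlength=6).astype(np.int64)
        cbase = np.zeros(6, dtype=np.int64)
        cbase[1:] = np.cumsum(counts)[:-1]
        mark = (sa % sa_sample_rate) == 0
        markrank = np.cumsum(mark) - 1
        vals = sa[mark]
        return cls(
            names=names,
            lengths=lengths,
            starts=starts,
            text=text,
            bwt=bwt,
            occ_ck=occ_ck,
            cbase=cbase,
            sa_mark=mark,
            sa_markrank=markrank.astype(np.int64),
            sa_vals=vals.astype(np.int64),
            sa_sample_rate=sa_sample_rate,
            colorspace=colorspace,
        )

    # -- basic queries ------------------------------------------------

    def __len__(self) -> int:
        return int(self.text.size)

    @property
    def genome_length(self) -> int:
        return int(self.lengths.sum())

    def default_min_mem_len(self) -> int:
        """ceil(log4 n) + 3, clamped to [13, 17]."""
        n = max(self.genome_length, 4)
        return int(min(17, max(13, math.ceil(math.log(n, 4)) + 3)))

    def fetch(self, start: int, end: int) -> str:
        return decode_seq(self.text[max(start, 0) : max(end, 0)])

    def to_local(self, gpos: int) -> tuple[int, int]:
        """Global offset -> (contig index, contig-local offset)."""
        i = int(np.searchsorted(self.starts, gpos, side="right")) - 1
        local = gpos - int(self.starts[i])
        if not (0 <= local < int(self.lengths[i])):
            raise ValueError(f"offset {gpos} falls on a contig separator")
        return i, local

    def contig_bounds(self, gpos: int) -> tuple[int, int]:
        i, _ = self.to_local(gpos)
        s = int(self.starts[i])
        return s, s + int(self.lengths[i])

    def oriented(self, read: str, strand: str) -> str:
        """Strand transform: reverse complement in base space, plain
        reversal in color space (colors are strand-symmetric)."""
        if strand == "+":
            return read
        return read[::-1] if self.colorspace else revcomp(read)

    # -- FM-index operations -------------------------------------------

    def backward_search(self, pattern: str) -> tuple[int, int]:
        """SA interval [lo, hi) of exact occurrences of `pattern`."""
        if not pattern:
            raise InputError("empty pattern")
        pat = encode_seq(pattern.upper())
        lo, hi = _backward_search(self.bwt, self.occ_ck, self.cbase, pat)
        return int(lo), int(hi)

    def locate(self, lo: int, hi: int, cap: Optional[int] = None) -> np.ndarray:
        """Text positions for BWT rows [lo, hi), first `cap` rows."""
        n = hi - lo
        if cap is not None:
            n = min(n, cap)
        out = np.empty(n, dtype=np.int64)
        for i in range(n):
            out[i] = _locate_row(
                self.bwt, self.occ_ck, self.cbase,
                self.sa_mark, self.sa_markrank, self.sa_vals, lo + i,
            )
        return out

    def count(self, pattern: str) -> int:
        lo, hi = self.backward_search(pattern)
        return hi - lo

    # -- seed extraction ----------------------------------------------

    def _collect(self, oriented: str, win_len: int, stride: int,
                 max_occ: int, extend: bool) -> np.ndarray:
        rcodes = _CODE[np.frombuffer(oriented.encode("ascii"), dtype=np.uint8)]
        if (rcodes == 255).any():
            raise InputError("read contains a non-IUPAC character")
        cap = 8192
        out = np.empty((cap, 3), dtype=np.int64)
        n = _collect_exact_seeds(
            self.bwt, self.occ_ck, self.cbase,
            self.sa_mark, self.sa_markrank, self.sa_vals,
            rcodes, win_len, stride, max_occ, self.text,
            extend, out,
        )
        return out[:n]

    def find_mem_seeds(
        self, read: str, min_mem_len: Optional[int] = None, max_occ: int = 1000
    ) -> list[Seed]:
        """Maximal exact matches of length >= min_mem_len, both strands.

        Each occurrence is individually maximal (extendable in neither
        direction on the text); per length-`min_mem_len` window at most
        `max_occ` occurrences are located, taken in suffix-array order.
        """
        if min_mem_len is None:
            min_mem_len = self.default_min_mem_len()
        read = read.upper()
        seeds: list[Seed] = []
        if len(read) < min_mem_len:
            return seeds
        for strand in "+-":
            oriented = self.oriented(read, strand)
            rows = self._collect(oriented, min_mem_len, 1, max_occ, True)
            if rows.size:
                rows = np.unique(rows, axis=0)
            for rs, gs, ln in rows:
                seeds.append(
                    Seed(int(rs), int(gs), int(ln), strand, SEED_MEM)
                )
        seeds.sort(key=lambda s: (s.strand, s.read_offset, s.genome_pos))
        return seeds

    def find_kmer_seeds(
        self, read: str, k: int = 13, max_occ: int = 1000
    ) -> list[Seed]:
        """Exact matches of the read's non-overlapping k-mer tiles, both
        strands, at most `max_occ` occurrences per tile."""
        read = read.upper()
        seeds: list[Seed] = []
        if len(read) < k:
            return seeds
        for strand in "+-":
            oriented = self.oriented(read, strand)
            rows = self._collect(oriented, k, k, max_occ, False)
            for rs, gs, ln in rows:
                seeds.append(
                    Seed(int(rs), int(gs), int(ln), strand, SEED_KMER)
                )
        seeds.sort(key=lambda s: (s.strand, s.read_offset, s.genome_pos))
        return seeds

    # -- persistence ----------------------------------------------------

    def save(self, path: str | os.PathLike) -> None:
        with open(path, "wb") as fh:
            self._savez(fh)

    def _savez(self, fh) -> None:
        np.savez_compressed(
            fh,
            version=np.int64(INDEX_FORMAT_VERSION),
            meta=np.frombuffer(
                json.dumps(
                    {
                        "names": self.names,
                        "sa_sample_rate": self.sa_sample_rate,
                        "colorspace": self.colorspace,
                    }
                ).encode(),
                dtype=np.uint8,
            ),
            lengths=self.lengths,
            starts=self.starts,
            text=self.text,
            bwt=self.bwt,
            occ_ck=self.occ_ck,
            cbase=self.cbase,
            sa_mark=self.sa_mark,
            sa_markrank=self.sa_markrank,
            sa_vals=self.sa_vals,
        )

    @classmethod
    def load(cls, path: str | os.PathLike) -> "ReferenceIndex":
        with np.load(path) as z:
            ver = int(z["version"])
            if ver != INDEX_FORMAT_VERSION:
                raise InputError(f"unsupported index version {ver}")
            meta = json.loads(z["meta"].tobytes().decode())
            return cls(
                names=meta["names"],
                lengths=z["lengths"],
                starts=z["starts"],
                text=z["text"],
                bwt=z["bwt"],
                occ_ck=z["occ_ck"],
                cbase=z["cbase"],
                sa_mark=z["sa_mark"],
                sa_markrank=z["sa_markrank"],
                sa_vals=z["sa_vals"],
                sa_sample_rate=meta["sa_sample_rate"],
                colorspace=meta["colorspace"],
            )


def build_index(
    fasta_path: str | os.PathLike,
    sa_sample_rate: int = 8,
    colorspace: bool = False,
) -> ReferenceIndex:
    """Build a :class:`ReferenceIndex` from a (possibly gzipped) FASTA."""
    records = list(read_sequences(fasta_path))
    if not records:
        raise InputError(f"{fasta_path}: empty FASTA")
    return ReferenceIndex.from_records(
        records, sa_sample_rate=sa_sample_rate, colorspace=colorspace
    )
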