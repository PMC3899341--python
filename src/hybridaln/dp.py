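"""Pairwise alignment kernels and alignment qualification.

Two alignment modes drive the pipelines:

* ``local`` — Smith-Waterman with affine gaps; unaligned read ends become
  soft clips.
* ``semiglobal`` — the whole read is aligned end to end against a mapping
  region, with gaps at the region ends free (used by the variable-length
  seed rescue path and by mate rescuing).

A gap of length L costs ``gap_open + L * gap_extend`` (both negative).
The matrix fill and traceback are delegated to Biopython's C
``PairwiseAligner``; this module owns the scoring conventions, CIGAR
construction, identity/edit-distance bookkeeping and the qualification
thresholds (local identity >= 90%, semi-global identity >= 65%, aligned
base fraction >= 80% by default).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from functools import lru_cache
from typing import Optional

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

from .index import Seed, SEED_VARLEN

MODE_LOCAL = "local"
MODE_SEMIGLOBAL = "semiglobal"

_ALPHABET = "ACGTN"


@dataclass(frozen=True)
class ScoringScheme:
    """Affine-gap scoring. The match reward is deliberately smaller than
    the mismatch/gap penalties so that runs of errors depress local scores
    (which is what makes the semi-global rescue path worthwhile)."""

    match_m: int = 1
    mismatch: int = -3
    gap_open: int = -5
    gap_extend: int = -2

    def __post_init__(self):
        if self.match_m <= 0:
            raise ValueError("match_m must be positive")
        if self.mismatch >= 0 or self.gap_open >= 0 or self.gap_extend >= 0:
            raise ValueError("penalties must be negative")
        if abs(self.mismatch) < self.match_m:
            raise ValueError("|mismatch| must be >= match_m")


@dataclass(frozen=True)
class Thresholds:
    """Qualification constraints on produced alignments (percent / fraction)."""

    min_id_local: float = 90.0
    min_id_global: float = 65.0
    min_align_frac: float = 0.80


@dataclass
class MappingRegion:
    """Half-open global window on the reference believed to contain the read."""

    start: int
    end: int
    strand: str = "+"

    def __post_init__(self):
        if self.start < 0 or self.end <= self.start:
            raise ValueError(f"bad region [{self.start}, {self.end})")

    def __len__(self) -> int:
        return self.end - self.start


@dataclass
class Alignment:
    """An extended hit. ``ref_pos`` is the 0-based leftmost aligned
    reference offset (global once the pipeline rebases it); ``seq`` is the
    oriented read (reverse-complemented for '-' strand alignments)."""

    read_id: str
    ref_pos: int
    cigar: list  # [(op, length)] with op in "MIDS"
    score: float
    identity: float  # percent, matches / aligned read bases
    aligned_fraction: float
    edit_distance: int
    mode: str
    strand: str = "+"
    mapq: int = 0
    seq: str = ""
    region: Optional[MappingRegion] = None

    @property
    def ref_len(self) -> int:
        return sum(n for op, n in self.cigar if op in "MD")

    @property
    def read_len(self) -> int:
        return sum(n for op, n in self.cigar if op in "MIS")

    @property
    def end(self) -> int:
        return self.ref_pos + self.ref_len

    @property
    def cigar_string(self) -> str:
        return "".join(f"{n}{op}" for op, n in self.cigar)

    @property
    def lead_clip(self) -> int:
        return self.cigar[0][1] if self.cigar and self.cigar[0][0] == "S" else 0


@lru_cache(maxsize=16)
def _matrix(scheme: ScoringScheme):
    m = np.full((5, 5), float(scheme.mismatch))
    np.fill_diagonal(m, float(scheme.match_m))
    m[4, 4] = float(scheme.mismatch)  # N never matches, not even N
    return substitution_matrices.Array(_ALPHABET, dims=2, data=m)


@lru_cache(maxsize=16)
def _aligner(scheme: ScoringScheme, mode: str) -> Align.PairwiseAligner:
    a = Align.PairwiseAligner()
    a.substitution_matrix = _matrix(scheme)
    # Biopython charges open + (L-1)*extend; we define open + L*extend
    a.open_gap_score = float(scheme.gap_open + scheme.gap_extend)
    a.extend_gap_score = float(scheme.gap_extend)
    if mode == MODE_LOCAL:
        a.mode = "local"
    else:
        a.mode = "global"
        a.end_deletion_score = 0.0  # reference flanks are free
    return a


def _from_paths(aln, read: str, region_seq: str, scheme: ScoringScheme,
                mode: str) -> Alignment:
    """Convert a Biopython alignment (target=region, query=read) to our
    Alignment, with ref_pos relative to the region start."""
    t_blocks, q_blocks = aln.aligned
    if len(t_blocks) == 0:  # nothing aligned at all (pathological scoring)
        return Alignment(
            read_id="", ref_pos=0, cigar=[("S", len(read))], score=float(aln.score),
            identity=0.0, aligned_fraction=0.0, edit_distance=len(read), mode=mode,
        )
    cigar: list = []
    matches = 0
    mismatches = 0
    ins = 0
    dele = 0
    q0 = int(q_blocks[0][0])
    if q0 > 0:
        cigar.append(("S" if mode == MODE_LOCAL else "I", q0))
        if mode != MODE_LOCAL:
            ins += q0
    for bi in range(len(t_blocks)):
        ts, te = int(t_blocks[bi][0]), int(t_blocks[bi][1])
        qs, qe = int(q_blocks[bi][0]), int(q_blocks[bi][1])
        if bi > 0:
            dq = qs - int(q_blocks[bi - 1][1])
            dt = ts - int(t_blocks[bi - 1][1])
            if dq > 0:
                cigar.append(("I", dq))
                ins += dq
            if dt > 0:
                cigar.append(("D", dt))
                dele += dt
        if te > ts:
            if cigar and cigar[-1][0] == "M":
                cigar[-1] = ("M", cigar[-1][1] + (te - ts))
            else:
                cigar.append(("M", te - ts))
            for k in range(te - ts):
                if region_seq[ts + k] == read[qs + k]:
                    matches += 1
                else:
                    mismatches += 1
    q_end = int(q_blocks[-1][1])
    tail = len(read) - q_end
    if tail > 0:
        cigar.append(("S" if mode == MODE_LOCAL else "I", tail))
        if mode != MODE_LOCAL:
            ins += tail
    aligned_bases = sum(n for op, n in cigar if op in "MI")
    identity = 100.0 * matches / aligned_bases if aligned_bases else 0.0
    return Alignment(
        read_id="",
        ref_pos=int(t_blocks[0][0]),
        cigar=cigar,
        score=float(aln.score),
        identity=identity,
        aligned_fraction=aligned_bases / len(read),
        edit_distance=mismatches + ins + dele,
        mode=mode,
    )


def sw_score(read: str, region_seq: str, scheme: Optional[ScoringScheme] = None
             ) -> float:
    """Optimal local alignment score only (no traceback; the fast path
    used for seed ranking)."""
    scheme = scheme or ScoringScheme()
    return float(_aligner(scheme, MODE_LOCAL).score(region_seq, read))


def smith_waterman(
    read: str, region_seq: str, scheme: Optional[ScoringScheme] = None
) -> tuple[float, Optional[Alignment]]:
    """Optimal local alignment with affine gaps and CIGAR traceback.

    Returns ``(score, Alignment)``; the alignment is ``None`` when no cell
    scores positive. Unaligned read ends are soft-clipped.
    """
    if not read or not region_seq:
        raise ValueError("empty sequence")
    scheme = scheme or ScoringScheme()
    alns = _aligner(scheme, MODE_LOCAL).align(region_seq, read)
    score = float(alns.score)
    if score <= 0:
        return 0.0, None
    return score, _from_paths(alns[0], read, region_seq, scheme, MODE_LOCAL)


def semi_global(
    read: str, region_seq: str, scheme: Optional[ScoringScheme] = None
) -> tuple[float, Alignment]:
    """Whole-read alignment against a region with free region end gaps."""
    if len(region_seq) < len(read):
        raise ValueError("region shorter than read")
    scheme = scheme or ScoringScheme()
    alns = _aligner(scheme, MODE_SEMIGLOBAL).align(region_seq, read)
    a = _from_paths(alns[0], read, region_seq, scheme, MODE_SEMIGLOBAL)
    return a.score, a


def qualify(a: Alignment, mode: Optional[str] = None,
            cfg: Optional[Thresholds] = None) -> bool:
    """True iff the alignment meets its mode's identity threshold and the
    aligned-base-fraction threshold."""
    cfg = cfg or Thresholds()
    mode = mode or a.mode
    min_id = cfg.min_id_local if mode == MODE_LOCAL else cfg.min_id_global
    return a.identity >= min_id and a.aligned_fraction >= cfg.min_align_frac


def default_margin(read_len: int) -> int:
    return math.ceil(0.1 * read_len) + 10


def region_from_seed(
    seed: Seed,
    read_len: int,
    bounds: tuple[int, int],
    margin: Optional[int] = None,
) -> MappingRegion:
    """Mapping region implied by a seed: the full-read placement the seed
    suggests, widened by a margin to tolerate indels, clamped to the
    seed's contig."""
    if margin is None:
        margin = default_margin(read_len)
    lo, hi = bounds
    start = max(lo, seed.genome_pos - seed.read_offset - margin)
    end = min(hi, seed.genome_pos + (read_len - seed.read_offset) + margin)
    if end <= start:  # degenerate contig edge
        start, end = lo, min(hi, lo + 1)
    return MappingRegion(start, end, seed.strand)


def varlen_seed(a: Alignment) -> Seed:
    """Reuse a local alignment as a variable-length seed: the implied
    full-read placement is recentred from the alignment's clipped start."""
    return Seed(
        read_offset=a.lead_clip,
        genome_pos=a.ref_pos,
        length=max(a.ref_len, 1),
        strand=a.strand,
        kind=SEED_VARLEN,
        score_q=a.score,
    )


def rescore(a: Alignment, read: str, ref_seq: str,
            scheme: Optional[ScoringScheme] = None) -> float:
    """Re-derive the DP score from the CIGAR (consistency checks).

    ``ref_seq`` must start at ``a.ref_pos``; ``read`` is the oriented read.
    """
    scheme = scheme or ScoringScheme()
    score = 0.0
    q = t = 0
    for op, n in a.cigar:
        if op == "S":
            q += n
        elif op == "M":
            for k in range(n):
                score += (
                    scheme.match_m
                    if read[q + k] == ref_seq[t + k] and read[q + k] != "N"
                    else scheme.mismatch
                )
            q += n
            t += n
        elif op == "I":
            score += scheme.gap_open + n * scheme.gap_extend
            q += n
        elif op == "D":
            score += scheme.gap_open + n * scheme.gap_extend
            t += n
    return score
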