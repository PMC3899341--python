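"""Paired-end alignment: weighted seed pairing, alignment-pair ranking and
read mate rescuing.

For a read pair, both ends are MEM-seeded and ranked exactly as in the
single-end pipeline.  High-quality seeds (local score >= a floor, default
30) from the two ends are then enumerated as candidate pairs; candidates
consistent with the library layout (FR for Illumina paired-end, FF for
SOLiD mate pairs) and the insert-size window are pushed on a max-heap
keyed by the pair weight

    w = (q1 + q2) / (m * (|S1| + |S2|))

where q_i is the end's optimal local alignment score against its seed's
mapping region and m the match score, so w is 1 for two perfect ends.  If
no candidate pair exists, the end with fewer high-quality seeds is
re-seeded with k-mer tiles, the new seeds merged and re-ranked, and the
pairing repeated — until a pair is found or both ends have been re-seeded.
Popped seed pairs are extended end-wise (local, with the semi-global
fallback); qualified alignment pairs are ranked by recomputed weight, then
ascending edit-distance sum.  Pairs that cannot be formed this way go to
mate rescuing: a confident alignment of one end (MAPQ >= 20) defines the
window where the mate must lie, and the mate is aligned there directly by
dynamic programming.  Reads that remain unpaired are reported through
their best single-end alignments.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass
from typing import Optional

import numpy as np

from . import dp, se
from .dp import Alignment, MODE_LOCAL, MODE_SEMIGLOBAL
from .index import ReferenceIndex, Seed
from .sam import attach_mapq
from .se import AlignerConfig


class InsertEstimateError(RuntimeError):
    """Too few uniquely-aligned proper pairs to estimate the insert size."""


@dataclass
class SeedPair:
    """A candidate pairing of one seed per end, weighted by Eq-style w."""

    seed1: Seed
    seed2: Seed
    weight_w: float


@dataclass
class AlignmentPair:
    aln1: Alignment
    aln2: Alignment
    weight_w: float
    edit_sum: int

    @property
    def insert(self) -> int:
        left = min(self.aln1.ref_pos, self.aln2.ref_pos)
        right = max(self.aln1.end, self.aln2.end)
        return right - left


def pair_weight(q1: float, q2: float, m: float, len1: int, len2: int) -> float:
    """Normalized seed/alignment pair weight in [0, 1]; 1 when both ends
    align perfectly."""
    if m <= 0:
        raise ValueError("match score must be positive")
    return (q1 + q2) / (m * (len1 + len2))


def _implied_span(seed: Seed, read_len: int) -> tuple[int, int]:
    left = seed.genome_pos - seed.read_offset
    return left, left + read_len


def _seeds_compatible(
    s1: Seed, s2: Seed, len1: int, len2: int,
    insert: tuple[float, float], nsd: float, orientation: str,
) -> bool:
    mean, sd = insert
    lo, hi = mean - nsd * sd, mean + nsd * sd
    a1, e1 = _implied_span(s1, len1)
    a2, e2 = _implied_span(s2, len2)
    if orientation == "fr":
        if s1.strand == s2.strand:
            return False
        (af, ef), (ar, er) = ((a1, e1), (a2, e2)) if s1.strand == "+" else (
            (a2, e2), (a1, e1)
        )
        implied = er - af
        return af <= ar and lo <= implied <= hi
    # FF (SOLiD mate pairs): same strand, either order
    if s1.strand != s2.strand:
        return False
    implied = max(e1, e2) - min(a1, a2)
    return lo <= implied <= hi


def pair_seeds(
    ranked1: list[Seed],
    ranked2: list[Seed],
    len1: int,
    len2: int,
    insert: tuple[float, float],
    cfg: AlignerConfig,
    index: Optional[ReferenceIndex] = None,
) -> list:
    """Enumerate qualified seed pairs into a max-heap (list for heapq).

    Only seeds whose score_q reaches the floor participate; candidates
    must agree with the orientation mode and the insert window
    mean +/- insert_nsd * sd.  Popping yields non-increasing weight.
    """
    floor = cfg.seed_score_floor
    hq1 = [s for s in ranked1 if s.score_q >= floor][: cfg.max_top_seeds]
    hq2 = [s for s in ranked2 if s.score_q >= floor][: cfg.max_top_seeds]
    heap: list = []
    tie = 0
    for s1 in hq1:
        for s2 in hq2:
            if not _seeds_compatible(
                s1, s2, len1, len2, insert, cfg.insert_nsd, cfg.orientation
            ):
                continue
            if index is not None:
                c1, _ = index.to_local(s1.genome_pos)
                c2, _ = index.to_local(s2.genome_pos)
                if c1 != c2:
                    continue
            w = pair_weight(
                s1.score_q, s2.score_q, cfg.scheme.match_m, len1, len2
            )
            heapq.heappush(
                heap, (-w, s1.genome_pos, s2.genome_pos, tie, SeedPair(s1, s2, w))
            )
            tie += 1
    return heap


def pop_pair(heap) -> Optional[SeedPair]:
    if not heap:
        return None
    return heapq.heappop(heap)[-1]


def _pair_ok(
    a1: Alignment, a2: Alignment, insert: tuple[float, float],
    cfg: AlignerConfig, index: ReferenceIndex,
) -> bool:
    mean, sd = insert
    lo, hi = mean - cfg.insert_nsd * sd, mean + cfg.insert_nsd * sd
    c1, _ = index.to_local(a1.ref_pos)
    c2, _ = index.to_local(a2.ref_pos)
    if c1 != c2:
        return False
    if cfg.orientation == "fr":
        if a1.strand == a2.strand:
            return False
        f, r = (a1, a2) if a1.strand == "+" else (a2, a1)
        span = r.end - f.ref_pos
        return f.ref_pos <= r.ref_pos and lo <= span <= hi
    if a1.strand != a2.strand:
        return False
    span = max(a1.end, a2.end) - min(a1.ref_pos, a2.ref_pos)
    return lo <= span <= hi


def estimate_insert_size(
    index: ReferenceIndex,
    read_pairs,
    cfg: Optional[AlignerConfig] = None,
) -> tuple[float, float]:
    """Estimate the library insert-size distribution from a sample.

    Ends are aligned in single-end mode; pairs where both ends have one
    unique qualified alignment, on the same contig in the configured
    orientation, contribute their observed outer distance.  Outliers
    beyond 3 x IQR of the quartiles are discarded.
    """
    cfg = cfg or AlignerConfig()
    inserts = []
    for n, (r1, r2) in enumerate(read_pairs):
        if n >= cfg.sample_n:
            break
        s1 = r1 if isinstance(r1, str) else r1.sequence
        s2 = r2 if isinstance(r2, str) else r2.sequence
        alns1 = se.align_single(index, s1, cfg)
        alns2 = se.align_single(index, s2, cfg)
        if len(alns1) != 1 or len(alns2) != 1:
            continue
        a1, a2 = alns1[0], alns2[0]
        c1, _ = index.to_local(a1.ref_pos)
        c2, _ = index.to_local(a2.ref_pos)
        if c1 != c2:
            continue
        if cfg.orientation == "fr":
            if a1.strand == a2.strand:
                continue
            f, r = (a1, a2) if a1.strand == "+" else (a2, a1)
            if f.ref_pos > r.ref_pos:
                continue
            inserts.append(r.end - f.ref_pos)
        else:
            if a1.strand != a2.strand:
                continue
            inserts.append(
                max(a1.end, a2.end) - min(a1.ref_pos, a2.ref_pos)
            )
    if len(inserts) < 100:
        raise InsertEstimateError(
            f"only {len(inserts)} usable pairs; pass --insert-mean/--insert-sd"
        )
    arr = np.asarray(inserts, dtype=float)
    q1, q3 = np.percentile(arr, [25, 75])
    iqr = q3 - q1
    kept = arr[(arr >= q1 - 3 * iqr) & (arr <= q3 + 3 * iqr)]
    return float(kept.mean()), float(kept.std(ddof=1)) if kept.size > 1 else 0.0


def rescue_mate(
    index: ReferenceIndex,
    anchored: Alignment,
    mate_read: str,
    insert: tuple[float, float],
    cfg: Optional[AlignerConfig] = None,
) -> Optional[Alignment]:
    """Align the mate by DP inside the window implied by its anchor.

    The anchor must be confident (MAPQ >= rescue_min_mapq); the window is
    the anchor's fragment placement extended by mean +/- nsd*sd, clamped
    to the anchor's contig.  Returns the mate alignment iff it qualifies.
    """
    cfg = cfg or AlignerConfig()
    if anchored.mapq < cfg.rescue_min_mapq:
        return None
    mean, sd = insert
    w = cfg.insert_nsd * sd
    pad = 16
    Lm = len(mate_read)
    clo, chi = index.contig_bounds(anchored.ref_pos)
    windows = []
    if cfg.orientation == "fr":
        mate_strand = "-" if anchored.strand == "+" else "+"
        if anchored.strand == "+":
            fs = anchored.ref_pos
            windows.append((fs + mean - w - Lm - pad, fs + mean + w + pad))
        else:
            fe = anchored.end
            windows.append((fe - mean - w - pad, fe - mean + w + Lm + pad))
    else:
        mate_strand = anchored.strand
        fs, fe = anchored.ref_pos, anchored.end
        windows.append((fs + mean - w - Lm - pad, fs + mean + w + pad))
        windows.append((fe - mean - w - pad, fe - mean + w + Lm + pad))
    oriented = index.oriented(mate_read, mate_strand)
    for wlo, whi in windows:
        lo = max(clo, int(wlo))
        hi = min(chi, int(whi))
        if hi - lo < Lm:
            continue
        region_seq = index.fetch(lo, hi)
        _, a = dp.smith_waterman(oriented, region_seq, cfg.scheme)
        chosen = None
        if a is not None and dp.qualify(a, MODE_LOCAL, cfg.thresholds):
            chosen = a
        else:
            _, g = dp.semi_global(oriented, region_seq, cfg.scheme)
            if dp.qualify(g, MODE_SEMIGLOBAL, cfg.thresholds):
                chosen = g
        if chosen is not None:
            chosen.ref_pos += lo
            chosen.strand = mate_strand
            chosen.seq = oriented
            return chosen
    return None


def _hq_count(ranked: list[Seed], floor: float) -> int:
    return sum(1 for s in ranked if s.score_q >= floor)


def align_pair(
    index: ReferenceIndex,
    read1: str,
    read2: str,
    cfg: Optional[AlignerConfig] = None,
    insert: tuple[float, float] = (500.0, 50.0),
    read_id: str = "pair",
) -> tuple[list[AlignmentPair], tuple[list[Alignment], list[Alignment]]]:
    """Align a read pair; returns (ranked alignment pairs, SE fallback).

    The fallback lists are populated only when no qualified pair could be
    produced (each end's best single-end alignments, possibly empty).
    """
    cfg = cfg or AlignerConfig()
    read1, read2 = read1.upper(), read2.upper()
    L1, L2 = len(read1), len(read2)
    oriented = {
        1: {"+": read1, "-": index.oriented(read1, "-")},
        2: {"+": read2, "-": index.oriented(read2, "-")},
    }
    seeds = {
        1: index.find_mem_seeds(read1, cfg.min_mem_len, cfg.max_occ),
        2: index.find_mem_seeds(read2, cfg.min_mem_len, cfg.max_occ),
    }
    ranked = {
        1: se.score_and_rank_seeds(index, read1, seeds[1], cfg.scheme),
        2: se.score_and_rank_seeds(index, read2, seeds[2], cfg.scheme),
    }
    reseeded = {1: False, 2: False}
    reads = {1: read1, 2: read2}

    heap = pair_seeds(ranked[1], ranked[2], L1, L2, insert, cfg, index)
    while not heap and not all(reseeded.values()):
        floor = cfg.seed_score_floor
        todo = sorted(
            (e for e in (1, 2) if not reseeded[e]),
            key=lambda e: (_hq_count(ranked[e], floor), e),
        )
        end = todo[0]
        reseeded[end] = True
        kseeds = index.find_kmer_seeds(reads[end], cfg.k, cfg.max_occ)
        if kseeds:
            seeds[end] = se._merge_seeds(seeds[end], kseeds)
            ranked[end] = se.score_and_rank_seeds(
                index, reads[end], seeds[end], cfg.scheme
            )
            heap = pair_seeds(ranked[1], ranked[2], L1, L2, insert, cfg, index)

    pairs: list[AlignmentPair] = []
    cache: dict = {}

    def _extended(endi: int, seed: Seed) -> Optional[Alignment]:
        key = (endi, seed.region.start, seed.region.end, seed.strand)
        if key not in cache:
            q, local = se.extend_seed(index, oriented[endi], seed, cfg)
            if q is None and local is not None and cfg.enable_semiglobal_rescue:
                q = se.semiglobal_rescue(index, oriented[endi], local, cfg)
            cache[key] = q
        return cache[key]

    popped = 0
    while heap and popped < cfg.max_pairs_extend and len(pairs) < cfg.max_reported:
        sp = pop_pair(heap)
        popped += 1
        a1 = _extended(1, sp.seed1)
        a2 = _extended(2, sp.seed2)
        if a1 is None or a2 is None:
            continue
        if not _pair_ok(a1, a2, insert, cfg, index):
            continue
        w = pair_weight(a1.score, a2.score, cfg.scheme.match_m, L1, L2)
        pairs.append(
            AlignmentPair(a1, a2, w, a1.edit_distance + a2.edit_distance)
        )

    se1: list[Alignment] = []
    se2: list[Alignment] = []
    if not pairs:
        se1 = se.align_single(index, read1, cfg, read_id)
        se2 = se.align_single(index, read2, cfg, read_id)
        if cfg.enable_mate_rescue:
            anchors = sorted(
                [(a, 1) for a in se1] + [(a, 2) for a in se2],
                key=lambda t: -t[0].mapq,
            )[: cfg.max_top_seeds]
            for anchor, endi in anchors:
                if anchor.mapq < cfg.rescue_min_mapq:
                    break
                mate = read2 if endi == 1 else read1
                r = rescue_mate(index, anchor, mate, insert, cfg)
                if r is None:
                    continue
                a1, a2 = (anchor, r) if endi == 1 else (r, anchor)
                if not _pair_ok(a1, a2, insert, cfg, index):
                    continue
                w = pair_weight(a1.score, a2.score, cfg.scheme.match_m, L1, L2)
                pairs.append(
                    AlignmentPair(a1, a2, w, a1.edit_distance + a2.edit_distance)
                )
                break

    # rank: weight desc, edit sum asc, leftmost first-end coordinate
    uniq: dict = {}
    for p in pairs:
        key = (p.aln1.ref_pos, p.aln1.strand, p.aln2.ref_pos, p.aln2.strand)
        prev = uniq.get(key)
        if prev is None or (-p.weight_w, p.edit_sum) < (-prev.weight_w, prev.edit_sum):
            uniq[key] = p
    out = sorted(
        uniq.values(), key=lambda p: (-p.weight_w, p.edit_sum, p.aln1.ref_pos)
    )[: cfg.max_reported]
    for p in out:
        p.aln1.read_id = read_id
        p.aln2.read_id = read_id
    attach_mapq([p.aln1 for p in out])
    attach_mapq([p.aln2 for p in out])
    if out:
        return out, ([], [])
    for a in se1 + se2:
        a.read_id = read_id
    return [], (se1[: cfg.max_reported], se2[: cfg.max_reported])
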