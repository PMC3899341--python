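"""Single-end alignment pipeline.

Stage order for one read:

1. MEM seeds on both strands.
2. Each seed's mapping region is scored with Smith-Waterman and the seeds
   are ranked by that score; the top-ranked seeds are extended with a full
   traceback.  A local alignment passing the local constraints is accepted.
3. If nothing qualified, the best local alignment is reused as a
   variable-length seed: a fresh region is derived from its implied
   full-read placement and a semi-global alignment is attempted under the
   (laxer) global constraints.  This captures reads whose errors are
   bunched — long mismatch runs and gaps depress local scores below the
   local identity bar, but the full-length alignment is still sound.
4. If still nothing, the read is re-seeded once with non-overlapping
   exact-match k-mer tiles (merged with the MEM seeds) and stages 2-3 run
   again.
5. An empty result marks the read unaligned.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from . import dp
from .dp import (
    Alignment,
    MappingRegion,
    ScoringScheme,
    Thresholds,
    MODE_LOCAL,
    MODE_SEMIGLOBAL,
)
from .index import ReferenceIndex, Seed
from .sam import attach_mapq


@dataclass
class AlignerConfig:
    """All pipeline knobs, with the tool's published defaults."""

    scheme: ScoringScheme = field(default_factory=ScoringScheme)
    thresholds: Thresholds = field(default_factory=Thresholds)
    min_mem_len: Optional[int] = None  # None -> index.default_min_mem_len()
    k: int = 13
    max_occ: int = 1000
    max_seeds_extend: int = 20
    max_reported: int = 10
    min_seed_score: float = 30.0  # in units of match_m = 1
    rescue_min_mapq: int = 20
    max_top_seeds: int = 100
    insert_nsd: float = 4.0
    orientation: str = "fr"  # 'fr' (Illumina PE) | 'ff' (SOLiD mate pairs)
    sample_n: int = 10000
    max_pairs_extend: int = 50
    enable_semiglobal_rescue: bool = True
    enable_mate_rescue: bool = True

    @property
    def seed_score_floor(self) -> float:
        # stated for match = +1; rescaled if the scheme differs
        return self.min_seed_score * self.scheme.match_m


def score_and_rank_seeds(
    index: ReferenceIndex,
    read: str,
    seeds: list[Seed],
    scheme: Optional[ScoringScheme] = None,
    margin: Optional[int] = None,
) -> list[Seed]:
    """Fill each seed's ``score_q`` (optimal local score of the read
    against the seed's mapping region), deduplicate seeds that collapse to
    the same (region, strand), and sort best-first."""
    scheme = scheme or ScoringScheme()
    L = len(read)
    oriented = {s: index.oriented(read, s) for s in "+-"}
    best: dict = {}
    for seed in seeds:
        region = dp.region_from_seed(
            seed, L, index.contig_bounds(seed.genome_pos), margin
        )
        key = (region.start, region.end, seed.strand)
        if key in best and best[key].length >= seed.length:
            continue
        seed.region = region
        seed.score_q = dp.sw_score(
            oriented[seed.strand], index.fetch(region.start, region.end), scheme
        )
        prev = best.get(key)
        if prev is None or seed.score_q > prev.score_q or (
            seed.score_q == prev.score_q and seed.length > prev.length
        ):
            best[key] = seed
    ranked = list(best.values())
    ranked.sort(
        key=lambda s: (-s.score_q, s.strand, s.region.start, s.read_offset)
    )
    return ranked


def extend_seed(
    index: ReferenceIndex,
    oriented: dict,
    seed: Seed,
    cfg: AlignerConfig,
) -> tuple[Optional[Alignment], Optional[Alignment]]:
    """Full local extension of one scored seed.

    Returns ``(qualified, local)`` where ``local`` is the traceback
    alignment regardless of qualification (used as a variable-length seed
    by the semi-global rescue) and ``qualified`` is the same alignment if
    it passed the local constraints.
    """
    region = seed.region
    read = oriented[seed.strand]
    if region is None:
        region = dp.region_from_seed(
            seed, len(read), index.contig_bounds(seed.genome_pos)
        )
    _, a = dp.smith_waterman(read, index.fetch(region.start, region.end), cfg.scheme)
    if a is None:
        return None, None
    a.ref_pos += region.start
    a.strand = seed.strand
    a.seq = read
    a.region = region
    return (a if dp.qualify(a, MODE_LOCAL, cfg.thresholds) else None), a


def semiglobal_rescue(
    index: ReferenceIndex,
    oriented: dict,
    local: Alignment,
    cfg: AlignerConfig,
) -> Optional[Alignment]:
    """Variable-length-seed rescue: recompute a region from the best local
    alignment and align the whole read semi-globally."""
    read = oriented[local.strand]
    vseed = dp.varlen_seed(local)
    region = dp.region_from_seed(
        vseed, len(read), index.contig_bounds(local.ref_pos)
    )
    region_seq = index.fetch(region.start, region.end)
    if len(region_seq) < len(read):
        return None
    _, g = dp.semi_global(read, region_seq, cfg.scheme)
    g.ref_pos += region.start
    g.strand = local.strand
    g.seq = read
    g.region = region
    if dp.qualify(g, MODE_SEMIGLOBAL, cfg.thresholds):
        return g
    return None


def _extend_stage(
    index: ReferenceIndex,
    oriented: dict,
    ranked: list[Seed],
    cfg: AlignerConfig,
) -> list[Alignment]:
    qualified: list[Alignment] = []
    best_local: Optional[Alignment] = None
    for seed in ranked[: cfg.max_seeds_extend]:
        if len(qualified) >= cfg.max_reported:
            break
        q, local = extend_seed(index, oriented, seed, cfg)
        if local is not None and (
            best_local is None or local.score > best_local.score
        ):
            best_local = local
        if q is not None:
            qualified.append(q)
    if not qualified and best_local is not None and cfg.enable_semiglobal_rescue:
        g = semiglobal_rescue(index, oriented, best_local, cfg)
        if g is not None:
            qualified.append(g)
    return qualified


def rank_alignments(alns: list[Alignment]) -> list[Alignment]:
    """Best-first order: score desc, then edit distance asc, then leftmost
    coordinate; duplicates of one placement collapse to the best."""
    seen: dict = {}
    for a in alns:
        key = (a.ref_pos, a.strand)
        prev = seen.get(key)
        if prev is None or (a.score, -a.edit_distance) > (prev.score, -prev.edit_distance):
            seen[key] = a
    out = list(seen.values())
    out.sort(key=lambda a: (-a.score, a.edit_distance, a.ref_pos, a.strand))
    return out


def _merge_seeds(mem: list[Seed], kmer: list[Seed]) -> list[Seed]:
    seen = {(s.read_offset, s.genome_pos, s.length, s.strand) for s in mem}
    merged = list(mem)
    for s in kmer:
        if (s.read_offset, s.genome_pos, s.length, s.strand) not in seen:
            merged.append(s)
    return merged


def align_single(
    index: ReferenceIndex,
    read: str,
    cfg: Optional[AlignerConfig] = None,
    read_id: str = "read",
) -> list[Alignment]:
    """Align one read; returns up to ``cfg.max_reported`` qualified
    alignments, best first, with MAPQs attached (empty list = unaligned)."""
    cfg = cfg or AlignerConfig()
    read = read.upper()
    oriented = {"+": read, "-": index.oriented(read, "-")}
    mem_seeds = index.find_mem_seeds(read, cfg.min_mem_len, cfg.max_occ)
    ranked = score_and_rank_seeds(index, read, mem_seeds, cfg.scheme)
    results = _extend_stage(index, oriented, ranked, cfg)
    if not results and len(read) >= cfg.k:
        kseeds = index.find_kmer_seeds(read, cfg.k, cfg.max_occ)
        if kseeds:
            ranked = score_and_rank_seeds(
                index, read, _merge_seeds(mem_seeds, kseeds), cfg.scheme
            )
            results = _extend_stage(index, oriented, ranked, cfg)
    results = rank_alignments(results)[: cfg.max_reported]
    for a in results:
        a.read_id = read_id
    attach_mapq(results)
    return results
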