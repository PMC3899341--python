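"""SOLiD color-space support.

SOLiD reads encode di-base transitions, not bases: color 0 joins identical
bases (AA/CC/GG/TT), 1 joins AC/CA/GT/TG, 2 joins AG/GA/CT/TC and 3 joins
AT/TA/CG/GC — equivalently, the XOR of the two bases' 2-bit codes.  The
genome is color-encoded contig by contig and the standard seeding/DP
pipelines run on color strings (a reverse-strand color read is simply the
reversed color string: the code is strand-symmetric).  A qualified
color-space alignment is then translated back to nucleotides by dynamic
programming under the guidance of the aligned reference bases, and the
translated read is re-aligned in base space with the same alignment mode
as its parent.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from . import dp, pe, se
from .dp import Alignment, MODE_LOCAL, MODE_SEMIGLOBAL
from .index import ReferenceIndex, revcomp
from .io_formats import SeqRecord
from .sam import attach_mapq
from .se import AlignerConfig

_BASE_BITS = {"A": 0, "C": 1, "G": 2, "T": 3}
_BITS_BASE = "ACGT"
# color digits <-> index letters (the FM-index works on its ACGT alphabet)
_COLOR_TO_LETTER = str.maketrans("0123.", "ACGTN")
_LETTER_TO_COLOR = str.maketrans("ACGTN", "0123.")


def encode_colors(bases: str) -> str:
    """Di-base color encoding; any pair touching a non-ACGT base gives '.'."""
    if len(bases) < 2:
        raise ValueError("need at least two bases to encode colors")
    bases = bases.upper()
    out = []
    for a, b in zip(bases, bases[1:]):
        if a in _BASE_BITS and b in _BASE_BITS:
            out.append(str(_BASE_BITS[a] ^ _BASE_BITS[b]))
        else:
            out.append(".")
    return "".join(out)


def decode_colors(primer: str, colors: str) -> str:
    """Resolve colors to bases from the primer anchor (error on '.')."""
    cur = _BASE_BITS[primer.upper()]
    out = []
    for c in colors:
        if c == ".":
            raise ValueError("cannot decode a missing color without guidance")
        cur ^= int(c)
        out.append(_BITS_BASE[cur])
    return "".join(out)


@dataclass
class ColorRead:
    """A SOLiD read: primer base + colors (first color joins primer to the
    first base, so `read_len` bases are carried by `read_len` colors)."""

    read_id: str
    primer_base: str
    colors: str
    quals: Optional[str] = None

    @classmethod
    def from_record(cls, rec: SeqRecord) -> "ColorRead":
        return cls(rec.id, rec.sequence[0], rec.sequence[1:], rec.quality)

    @property
    def n_bases(self) -> int:
        return len(self.colors)

    def stripped(self) -> str:
        """Primer-independent transition colors (length n_bases - 1)."""
        return self.colors[1:]


def color_index_records(records) -> list[SeqRecord]:
    """Color-encode genome contigs, mapping color digits onto the index
    alphabet (0123. -> ACGTN)."""
    out = []
    for rec in records:
        rid, seq = (rec.id, rec.sequence) if hasattr(rec, "id") else rec
        out.append(SeqRecord(rid, encode_colors(seq).translate(_COLOR_TO_LETTER)))
    return out


def build_color_index(records, sa_sample_rate: int = 8) -> ReferenceIndex:
    return ReferenceIndex.from_records(
        color_index_records(records), sa_sample_rate=sa_sample_rate,
        colorspace=True,
    )


def _translate_dp(
    transitions: str,
    guide: list,
    anchor: Optional[tuple[str, str]] = None,
    trans_cost: float = 1.0,
    emit_cost: float = 1.0,
) -> tuple[str, float]:
    """Min-cost base sequence for a color read.

    ``transitions`` are the L-1 colors joining L bases; ``guide[i]`` is the
    reference base aligned to read base i (None where the alignment gives
    no guidance).  A transition inconsistent with its observed color costs
    ``trans_cost`` (missing colors are free); emitting a base different
    from its guide costs ``emit_cost``.  ``anchor`` optionally ties the
    first base to (anchor_base, anchor_color).  This makes an isolated
    color error resolve to a single color correction instead of cascading
    through every downstream base.
    """
    L = len(transitions) + 1
    if len(guide) != L:
        raise ValueError("guide length must equal the number of read bases")

    def emit(i: int, b: int) -> float:
        g = guide[i]
        if g is None or g not in _BASE_BITS:
            return 0.0
        return 0.0 if _BASE_BITS[g] == b else emit_cost

    INF = float("inf")
    cost = [[INF] * 4 for _ in range(L)]
    back = [[0] * 4 for _ in range(L)]
    for b in range(4):
        c0 = emit(0, b)
        if anchor is not None:
            ab, ac = anchor
            if ac != "." and ab in _BASE_BITS:
                c0 += 0.0 if (_BASE_BITS[ab] ^ b) == int(ac) else trans_cost
        cost[0][b] = c0
    for i in range(1, L):
        col = transitions[i - 1]
        for b in range(4):
            best, bb = INF, 0
            for p in range(4):
                t = 0.0
                if col != "." and (p ^ b) != int(col):
                    t = trans_cost
                c = cost[i - 1][p] + t
                if c < best:
                    best, bb = c, p
            cost[i][b] = best + emit(i, b)
            back[i][b] = bb
    # final state: minimal cost, prefer the guide base, then A<C<G<T
    def _rank(b: int) -> tuple:
        g = guide[L - 1]
        pref = 0 if (g in _BASE_BITS and _BASE_BITS[g] == b) else 1
        return (cost[L - 1][b], pref, b)

    b = min(range(4), key=_rank)
    total = cost[L - 1][b]
    out = [b]
    for i in range(L - 1, 0, -1):
        b = back[i][b]
        out.append(b)
    return "".join(_BITS_BASE[x] for x in reversed(out)), total


def _guide_from_alignment(a: Alignment, ref_bases: str) -> list:
    """Per-read-base reference guidance from a color alignment's CIGAR.

    ``ref_bases`` must start at the base coordinate equal to the color
    alignment's (contig-local) start; a color aligned at reference color
    position t constrains read bases i and i+1 to reference bases t, t+1.
    """
    n_bases = sum(n for op, n in a.cigar if op in "MIS") + 1
    guide: list = [None] * n_bases
    q = t = 0
    for op, n in a.cigar:
        if op in "SI":
            q += n
        elif op == "D":
            t += n
        elif op == "M":
            for k in range(n):
                if t + k < len(ref_bases):
                    guide[q + k] = ref_bases[t + k]
                if t + k + 1 < len(ref_bases):
                    guide[q + k + 1] = ref_bases[t + k + 1]
            q += n
            t += n
    return guide


def translate_alignment(
    color_read: ColorRead, ref_bases: str, color_alignment: Alignment
) -> str:
    """Translate a color read to bases under a color alignment's guidance.

    ``ref_bases`` is the nucleotide reference starting at the base
    coordinate matching the color alignment's start.  The oriented
    transition colors are taken from the alignment's stored sequence when
    present (reverse-strand reads are reversed color strings), otherwise
    from the read.
    """
    if color_alignment.seq:
        transitions = color_alignment.seq.translate(_LETTER_TO_COLOR)
    else:
        transitions = color_read.stripped()
    guide = _guide_from_alignment(color_alignment, ref_bases)
    anchor = None
    if color_alignment.strand == "+" and not color_alignment.lead_clip:
        anchor = (color_read.primer_base, color_read.colors[0])
    bases, _ = _translate_dp(transitions, guide, anchor)
    return bases


def translated_quality(cread: ColorRead, strand: str) -> Optional[str]:
    """Base qualities from color qualities: min of the adjacent colors."""
    if cread.quals is None:
        return None
    q = cread.quals
    out = [q[0]] + [min(q[i], q[i + 1]) for i in range(len(q) - 1)]
    s = "".join(out)
    return s[::-1] if strand == "-" else s


def _color_local_start(color_index: ReferenceIndex, a: Alignment) -> tuple[int, int]:
    return color_index.to_local(a.ref_pos)


def _realign_translated(
    nuc_index: ReferenceIndex,
    translated: str,
    contig_idx: int,
    local_start: int,
    color_aln: Alignment,
    cfg: AlignerConfig,
) -> Optional[Alignment]:
    """Re-align the translated bases in base space, same mode as parent."""
    L = len(translated)
    cstart = int(nuc_index.starts[contig_idx])
    cend = cstart + int(nuc_index.lengths[contig_idx])
    margin = dp.default_margin(L)
    implied = cstart + local_start - color_aln.lead_clip
    lo = max(cstart, implied - margin)
    hi = min(cend, implied + L + margin)
    region_seq = nuc_index.fetch(lo, hi)
    if color_aln.mode == MODE_LOCAL:
        _, a = dp.smith_waterman(translated, region_seq, cfg.scheme)
        if a is None or not dp.qualify(a, MODE_LOCAL, cfg.thresholds):
            return None
    else:
        if len(region_seq) < L:
            return None
        _, a = dp.semi_global(translated, region_seq, cfg.scheme)
        if not dp.qualify(a, MODE_SEMIGLOBAL, cfg.thresholds):
            return None
    a.ref_pos += lo
    a.strand = color_aln.strand
    a.seq = translated
    return a


def _translate_and_realign(
    nuc_index: ReferenceIndex,
    color_index: ReferenceIndex,
    cread: ColorRead,
    color_aln: Alignment,
    cfg: AlignerConfig,
) -> Optional[Alignment]:
    ci, local = _color_local_start(color_index, color_aln)
    cstart = int(nuc_index.starts[ci])
    ref_bases = nuc_index.fetch(
        cstart + local, cstart + local + color_aln.ref_len + 1
    )
    translated = translate_alignment(cread, ref_bases, color_aln)
    a = _realign_translated(nuc_index, translated, ci, local, color_aln, cfg)
    if a is not None:
        a.read_id = cread.read_id
        a.mapq = color_aln.mapq
    return a


def align_color_read(
    nuc_index: ReferenceIndex,
    color_index: ReferenceIndex,
    cread: ColorRead,
    cfg: Optional[AlignerConfig] = None,
) -> list[Alignment]:
    """Align one color read; reported alignments are base-space.

    The primer base and its adjacent color are stripped; the remaining
    transition colors run through the standard single-end pipeline against
    the color genome; each qualified color alignment is translated to
    bases and re-aligned in base space with its parent's mode.
    """
    cfg = cfg or AlignerConfig()
    stripped = cread.stripped().translate(_COLOR_TO_LETTER)
    color_alns = se.align_single(color_index, stripped, cfg, cread.read_id)
    out = []
    for ca in color_alns:
        a = _translate_and_realign(nuc_index, color_index, cread, ca, cfg)
        if a is not None:
            out.append(a)
    out = se.rank_alignments(out)[: cfg.max_reported]
    attach_mapq(out)
    for a in out:
        a.read_id = cread.read_id
    return out


def align_color_pair(
    nuc_index: ReferenceIndex,
    color_index: ReferenceIndex,
    cread1: ColorRead,
    cread2: ColorRead,
    cfg: Optional[AlignerConfig] = None,
    insert: tuple[float, float] = (200.0, 20.0),
) -> tuple[list[pe.AlignmentPair], tuple[list[Alignment], list[Alignment]]]:
    """Mate-paired color alignment (FF orientation by default).

    The paired-end machinery runs in color space; resulting color
    alignment pairs (including mate rescues) are translated and re-aligned
    in base space end by end.
    """
    cfg = cfg or AlignerConfig()
    if cfg.orientation == "fr":
        from dataclasses import replace as _rep

        cfg = _rep(cfg, orientation="ff")
    s1 = cread1.stripped().translate(_COLOR_TO_LETTER)
    s2 = cread2.stripped().translate(_COLOR_TO_LETTER)
    cpairs, (cse1, cse2) = pe.align_pair(
        color_index, s1, s2, cfg, insert, read_id=cread1.read_id
    )
    pairs = []
    for p in cpairs:
        a1 = _translate_and_realign(nuc_index, color_index, cread1, p.aln1, cfg)
        a2 = _translate_and_realign(nuc_index, color_index, cread2, p.aln2, cfg)
        if a1 is None or a2 is None:
            continue
        pairs.append(
            pe.AlignmentPair(
                a1, a2,
                pe.pair_weight(
                    a1.score, a2.score, cfg.scheme.match_m,
                    cread1.n_bases, cread2.n_bases,
                ),
                a1.edit_distance + a2.edit_distance,
            )
        )
    pairs.sort(key=lambda p: (-p.weight_w, p.edit_sum, p.aln1.ref_pos))
    attach_mapq([p.aln1 for p in pairs])
    attach_mapq([p.aln2 for p in pairs])
    if pairs:
        return pairs[: cfg.max_reported], ([], [])
    se1 = [
        a for ca in cse1
        if (a := _translate_and_realign(nuc_index, color_index, cread1, ca, cfg))
    ]
    se2 = [
        a for ca in cse2
        if (a := _translate_and_realign(nuc_index, color_index, cread2, ca, cfg))
    ]
    return [], (se1[: cfg.max_reported], se2[: cfg.max_reported])
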