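"""MAPQ assignment and SAM emission (via pysam).

MAPQ uses a score-gap rule on the ranked alignment list of a read:
ambiguous best placements get 0, a unique alignment with no runner-up gets
the 60 cap, and otherwise the quality scales with the relative score gap
between the best and second-best placements.  All reported alignments of
one read carry the primary's MAPQ (secondaries are flagged 0x100).
"""

from __future__ import annotations

from typing import Optional

import pysam

from .dp import Alignment

MAPQ_CAP = 60

_CIGAR_CODE = {"M": 0, "I": 1, "D": 2, "N": 3, "S": 4}

FLAG_PAIRED = 0x1
FLAG_PROPER = 0x2
FLAG_UNMAPPED = 0x4
FLAG_MATE_UNMAPPED = 0x8
FLAG_REVERSE = 0x10
FLAG_MATE_REVERSE = 0x20
FLAG_FIRST = 0x40
FLAG_SECOND = 0x80
FLAG_SECONDARY = 0x100


def compute_mapq(
    best: Alignment, second: Optional[Alignment], n_best: int
) -> int:
    """PHRED-style mapping quality from the ranked alignments of a read.

    ``n_best`` is the number of distinct co-optimal placements; ``second``
    the best strictly-worse placement (or None).
    """
    if n_best >= 2:
        return 0
    if second is None:
        return MAPQ_CAP
    if best.score <= 0:
        return 0
    q = round(MAPQ_CAP * (best.score - second.score) / best.score)
    return int(min(max(q, 0), MAPQ_CAP))


def attach_mapq(ranked: list[Alignment]) -> None:
    """Set MAPQ on a best-first list of distinct placements of one read."""
    if not ranked:
        return
    best = ranked[0]
    n_best = sum(1 for a in ranked if a.score == best.score)
    second = next((a for a in ranked if a.score < best.score), None)
    q = compute_mapq(best, second, n_best)
    for a in ranked:
        a.mapq = q


def header_dict(index, program_args: str = "") -> dict:
    return {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [
            {"SN": name, "LN": int(length)}
            for name, length in zip(index.names, index.lengths)
        ],
        "PG": [
            {"ID": "hybridaln", "PN": "hybridaln", "CL": program_args or "hybridaln"}
        ],
        "RG": [{"ID": "default", "SM": "default"}],
    }


class SamWriter:
    """Streams alignments for single reads and read pairs to a SAM file."""

    def __init__(self, path, index, program_args: str = ""):
        self.index = index
        self._fh = pysam.AlignmentFile(
            str(path), "wh", header=pysam.AlignmentHeader.from_dict(
                header_dict(index, program_args)
            ),
        )

    def close(self):
        self._fh.close()

    def __enter__(self):
        return self

    def __exit__(self, *exc):
        self.close()

    # -- record assembly -------------------------------------------------

    def _oriented_qual(self, qual: Optional[str], strand: str) -> Optional[str]:
        if qual is None:
            return None
        return qual[::-1] if strand == "-" else qual

    def _segment(
        self,
        read_id: str,
        seq: str,
        qual: Optional[str],
        a: Optional[Alignment],
        flag: int,
    ) -> pysam.AlignedSegment:
        seg = pysam.AlignedSegment(self._fh.header)
        seg.query_name = read_id
        seg.flag = flag
        if a is None:
            seg.reference_id = -1
            seg.reference_start = -1
            seg.mapping_quality = 0
            seg.query_sequence = seq
            if qual is not None:
                seg.query_qualities = pysam.qualitystring_to_array(qual)
        else:
            tid, local = self.index.to_local(a.ref_pos)
            seg.reference_id = tid
            seg.reference_start = local
            seg.mapping_quality = a.mapq
            seg.cigartuples = [(_CIGAR_CODE[op], n) for op, n in a.cigar]
            seg.query_sequence = a.seq or seq
            oq = self._oriented_qual(qual, a.strand)
            if oq is not None:
                seg.query_qualities = pysam.qualitystring_to_array(oq)
            seg.set_tag("NM", int(a.edit_distance))
            seg.set_tag("AS", int(a.score))
            seg.set_tag("RG", "default")
        return seg

    @staticmethod
    def _base_flag(a: Optional[Alignment], secondary: bool) -> int:
        flag = 0
        if a is None:
            return FLAG_UNMAPPED
        if a.strand == "-":
            flag |= FLAG_REVERSE
        if secondary:
            flag |= FLAG_SECONDARY
        return flag

    # -- public emit methods ----------------------------------------------

    def write_single(
        self, read_id: str, seq: str, qual: Optional[str], alns: list[Alignment]
    ) -> None:
        if not alns:
            self._fh.write(self._segment(read_id, seq, qual, None, FLAG_UNMAPPED))
            return
        for i, a in enumerate(alns):
            self._fh.write(
                self._segment(read_id, seq, qual, a, self._base_flag(a, i > 0))
            )

    def _mate_flags(self, a1, a2) -> tuple[int, int]:
        f1 = FLAG_PAIRED | FLAG_FIRST
        f2 = FLAG_PAIRED | FLAG_SECOND
        f1 |= self._base_flag(a1, False) & ~FLAG_SECONDARY
        f2 |= self._base_flag(a2, False) & ~FLAG_SECONDARY
        if a1 is None:
            f2 |= FLAG_MATE_UNMAPPED
        elif a1.strand == "-":
            f2 |= FLAG_MATE_REVERSE
        if a2 is None:
            f1 |= FLAG_MATE_UNMAPPED
        elif a2.strand == "-":
            f1 |= FLAG_MATE_REVERSE
        return f1, f2

    def _set_mate(self, seg, mate: Optional[Alignment]):
        if mate is None:
            # SAM convention: unmapped mate placed at this record's position
            seg.next_reference_id = seg.reference_id
            seg.next_reference_start = seg.reference_start
            return
        tid, local = self.index.to_local(mate.ref_pos)
        seg.next_reference_id = tid
        seg.next_reference_start = local

    def write_pair(
        self,
        read_id: str,
        seq1: str,
        qual1: Optional[str],
        seq2: str,
        qual2: Optional[str],
        pairs: list,
        fallback: tuple[list, list] = ((), ()),
    ) -> None:
        """Emit one read pair: either its ranked AlignmentPairs (proper
        pairs; secondaries after the first) or the per-end SE fallback."""
        if pairs:
            for i, p in enumerate(pairs):
                a1, a2 = p.aln1, p.aln2
                f1, f2 = self._mate_flags(a1, a2)
                f1 |= FLAG_PROPER
                f2 |= FLAG_PROPER
                if i > 0:
                    f1 |= FLAG_SECONDARY
                    f2 |= FLAG_SECONDARY
                s1 = self._segment(read_id, seq1, qual1, a1, f1)
                s2 = self._segment(read_id, seq2, qual2, a2, f2)
                self._set_mate(s1, a2)
                self._set_mate(s2, a1)
                left = min(a1.ref_pos, a2.ref_pos)
                right = max(a1.end, a2.end)
                tlen = right - left
                s1.template_length = tlen if a1.ref_pos <= a2.ref_pos else -tlen
                s2.template_length = -s1.template_length
                self._fh.write(s1)
                self._fh.write(s2)
            return
        se1, se2 = fallback
        a1 = se1[0] if se1 else None
        a2 = se2[0] if se2 else None
        f1, f2 = self._mate_flags(a1, a2)
        for i, a in enumerate(se1 or [None]):
            f = f1 | (FLAG_SECONDARY if i > 0 else 0)
            seg = self._segment(read_id, seq1, qual1, a, f)
            self._set_mate(seg, a2)
            if a is None and a2 is None:
                seg.next_reference_id = -1
                seg.next_reference_start = -1
            self._fh.write(seg)
        for i, a in enumerate(se2 or [None]):
            f = f2 | (FLAG_SECONDARY if i > 0 else 0)
            seg = self._segment(read_id, seq2, qual2, a, f)
            self._set_mate(seg, a1)
            if a is None and a1 is None:
                seg.next_reference_id = -1
                seg.next_reference_start = -1
            self._fh.write(seg)
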