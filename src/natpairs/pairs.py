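"""Genome-wide NAT-pair detection and typing.

A NAT pair is two transcripts on opposite strands of the same chromosome
whose genomic spans overlap by at least ``min_overlap`` bp (default 25).
Each pair is typed by orientation — enclosed (one span contains the other),
divergent (head-to-head, 5'-end overlap) or convergent (tail-to-tail,
3'-end overlap) — and by the coding capacity of its members.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Union

import pandas as pd
from intervaltree import IntervalTree

from .annotation import Transcript

__all__ = [
    "NATPair",
    "span_overlap",
    "exon_overlap",
    "classify_orientation",
    "scan_pairs",
    "pairs_to_frame",
]

ORIENTATIONS = ("enclosed", "divergent", "convergent")
CODING_CLASSES = ("coding_coding", "coding_noncoding", "noncoding_noncoding")

Interval = tuple[int, int]


@dataclass(frozen=True)
class NATPair:
    """An opposite-strand transcript pair with its overlap interval.

    ``plus``/``minus`` are the + and - strand members.  For coding-noncoding
    pairs the sense member is the coding transcript and the antisense member
    the lncRNA; otherwise sense is the + strand member by convention.
    """

    plus: Transcript
    minus: Transcript
    overlap_start: int
    overlap_end: int
    overlap_len: int
    orientation: str
    coding_class: str
    sense_id: str
    antisense_id: str

    @property
    def chrom(self) -> str:
        return self.plus.chrom

    @property
    def sense(self) -> Transcript:
        return self.plus if self.plus.transcript_id == self.sense_id else self.minus

    @property
    def antisense(self) -> Transcript:
        return self.minus if self.plus.transcript_id == self.sense_id else self.plus

    @property
    def key(self) -> tuple[str, str]:
        return (self.sense_id, self.antisense_id)


def _as_interval(x: Union[Transcript, Interval]) -> Interval:
    if isinstance(x, Transcript):
        return (x.start, x.end)
    return (int(x[0]), int(x[1]))


def span_overlap(
    a: Union[Transcript, Interval], b: Union[Transcript, Interval]
) -> tuple[int, Optional[int], Optional[int]]:
    """Overlap of two 1-based inclusive intervals on one chromosome.

    Returns (overlap_len, overlap_start, overlap_end); the coordinates are
    None when the intervals are disjoint.  Passing transcripts from
    different chromosomes is a caller bug and raises.
    """
    if isinstance(a, Transcript) and isinstance(b, Transcript) and a.chrom != b.chrom:
        raise ValueError(
            f"span_overlap on different chromosomes: {a.chrom} vs {b.chrom}"
        )
    (a1, a2), (b1, b2) = _as_interval(a), _as_interval(b)
    start, end = max(a1, b1), min(a2, b2)
    if start > end:
        return 0, None, None
    return end - start + 1, start, end


def exon_overlap(a: Transcript, b: Transcript) -> tuple[int, Optional[int], Optional[int]]:
    """Total overlap between the exon unions of two transcripts.

    Returns (total_bp, hull_start, hull_end) of the intersecting pieces.
    """
    total, lo, hi = 0, None, None
    for s1, e1 in a.exons:
        for s2, e2 in b.exons:
            s, e = max(s1, s2), min(e1, e2)
            if s <= e:
                total += e - s + 1
                lo = s if lo is None else min(lo, s)
                hi = e if hi is None else max(hi, e)
    return total, lo, hi


def classify_orientation(a: Transcript, b: Transcript) -> str:
    """Orientation class of an overlapping opposite-strand pair.

    Containment in either direction (boundaries included, identical spans
    too) is enclosed.  Otherwise, with P the + strand span [p1,p2] and M the
    - strand span [m1,m2]: the overlap covering P's 5' end and M's 5' end
    (m1 < p1 <= m2 < p2) is divergent (head-to-head); the overlap covering
    both 3' ends (p1 < m1 <= p2 < m2) is convergent (tail-to-tail).
    """
    if a.strand == b.strand:
        raise ValueError(
            f"classify_orientation needs opposite strands "
            f"({a.transcript_id}, {b.transcript_id} both {a.strand})"
        )
    ov, _, _ = span_overlap((a.start, a.end), (b.start, b.end))
    if ov == 0:
        raise ValueError(
            f"classify_orientation on disjoint spans "
            f"({a.transcript_id}, {b.transcript_id})"
        )
    p = a if a.strand == "+" else b
    m = b if p is a else a
    if (p.start <= m.start and m.end <= p.end) or (m.start <= p.start and p.end <= m.end):
        return "enclosed"
    if m.start < p.start <= m.end < p.end:
        return "divergent"
    if p.start < m.start <= p.end < m.end:
        return "convergent"
    raise AssertionError("unreachable: overlap without a valid orientation")


def _coding_class(a: Transcript, b: Transcript) -> str:
    for t in (a, b):
        if t.coding not in ("coding", "noncoding"):
            raise ValueError(
                f"transcript {t.transcript_id} entering the pair scan has "
                "unresolved coding capacity"
            )
    n = (a.coding == "coding") + (b.coding == "coding")
    return CODING_CLASSES[2 - n]


def _make_pair(plus: Transcript, minus: Transcript, ov: int, lo: int, hi: int) -> NATPair:
    cclass = _coding_class(plus, minus)
    if cclass == "coding_noncoding":
        sense = plus if plus.coding == "coding" else minus
    else:
        sense = plus
    anti = minus if sense is plus else plus
    return NATPair(
        plus=plus,
        minus=minus,
        overlap_start=lo,
        overlap_end=hi,
        overlap_len=ov,
        orientation=classify_orientation(plus, minus),
        coding_class=cclass,
        sense_id=sense.transcript_id,
        antisense_id=anti.transcript_id,
    )


def scan_pairs(
    transcripts: Sequence[Transcript],
    min_overlap: int = 25,
    overlap_mode: str = "span",
) -> list[NATPair]:
    """All opposite-strand pairs with overlap >= ``min_overlap`` bp.

    ``overlap_mode`` selects whether the threshold applies to the genomic
    spans ("span", default) or to the exon unions ("exon").  A transcript
    may appear in many pairs; output is duplicate-free and sorted by
    (chrom, overlap_start, sense_id, antisense_id).
    """
    if overlap_mode not in ("span", "exon"):
        raise ValueError(f"overlap_mode must be 'span' or 'exon', got {overlap_mode!r}")
    by_chrom: dict[str, list[Transcript]] = {}
    for t in transcripts:
        by_chrom.setdefault(t.chrom, []).append(t)
    pairs: list[NATPair] = []
    for chrom_ts in by_chrom.values():
        minus_tree = IntervalTree()
        minus_by_id: dict[str, Transcript] = {}
        for t in chrom_ts:
            if t.strand == "-":
                minus_tree.addi(t.start, t.end + 1, t.transcript_id)
                minus_by_id[t.transcript_id] = t
        for p in chrom_ts:
            if p.strand != "+":
                continue
            for hit in minus_tree.overlap(p.start, p.end + 1):
                m = minus_by_id[hit.data]
                if overlap_mode == "span":
                    ov, lo, hi = span_overlap(p, m)
                else:
                    ov, lo, hi = exon_overlap(p, m)
                if ov >= min_overlap and lo is not None:
                    pairs.append(_make_pair(p, m, ov, lo, hi))
    pairs.sort(key=lambda x: (x.chrom, x.overlap_start, x.sense_id, x.antisense_id))
    return pairs


def pairs_to_frame(pairs: Sequence[NATPair]) -> pd.DataFrame:
    """Tabular view of a pair list, one row per pair."""
    rows = []
    for p in pairs:
        s, a = p.sense, p.antisense
        rows.append(
            {
                "chrom": p.chrom,
                "sense_id": s.transcript_id,
                "sense_start": s.start,
                "sense_end": s.end,
                "antisense_id": a.transcript_id,
                "antisense_start": a.start,
                "antisense_end": a.end,
                "overlap_len": p.overlap_len,
                "orientation": p.orientation,
                "coding_class": p.coding_class,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "chrom", "sense_id", "sense_start", "sense_end",
            "antisense_id", "antisense_start", "antisense_end",
            "overlap_len", "orientation", "coding_class",
        ],
    )
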