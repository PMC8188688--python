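"""lncRNA classification cascade.

Splits an annotated transcriptome into mRNA, lincRNA and lncNAT, after
excluding small noncoding RNAs (supplied as an id list) and transcripts
shorter than the long-noncoding length floor.  Coding capacity comes from an
override table when available and otherwise from a longest-ORF heuristic.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

from intervaltree import IntervalTree

from .annotation import Transcript

__all__ = [
    "LncClass",
    "spliced_length",
    "longest_orf_codons",
    "assign_coding",
    "classify_lnc",
]

CATEGORIES = ("mRNA", "lincRNA", "lncNAT", "excluded_smallRNA", "excluded_short")

_STOPS = frozenset({"TAA", "TAG", "TGA"})


@dataclass(frozen=True)
class LncClass:
    transcript_id: str
    category: str

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")


def spliced_length(t: Transcript) -> int:
    """Sum of exon lengths in bp (mature transcript length)."""
    return sum(e - s + 1 for s, e in t.exons)


def longest_orf_codons(sequence: str) -> int:
    """Longest ATG->stop open reading frame in the three forward frames.

    Returns the codon count from ATG up to (excluding) the stop codon;
    an ATG run that never reaches a stop does not count as an ORF.
    """
    seq = sequence.upper().replace("U", "T")
    best = 0
    for frame in range(3):
        start = None
        for i in range(frame, len(seq) - 2, 3):
            codon = seq[i : i + 3]
            if start is None:
                if codon == "ATG":
                    start = i
            elif codon in _STOPS:
                best = max(best, (i - start) // 3)
                start = None
    return best


def assign_coding(
    t: Transcript,
    overrides: Optional[Mapping[str, str]] = None,
    min_orf_codons: int = 100,
    sequence: Optional[str] = None,
) -> str:
    """Resolve a transcript's coding capacity.

    An override flag wins outright; otherwise the transcript is coding iff
    its longest forward-strand ORF reaches ``min_orf_codons`` codons.  With
    neither an override nor a sequence the pre-set flag is used, and an
    unresolved flag is an error.
    """
    if overrides and t.transcript_id in overrides:
        flag = overrides[t.transcript_id]
        if flag not in ("coding", "noncoding"):
            raise ValueError(
                f"override for {t.transcript_id} must be coding/noncoding, got {flag!r}"
            )
        return flag
    if sequence is not None:
        return "coding" if longest_orf_codons(sequence) >= min_orf_codons else "noncoding"
    if t.coding in ("coding", "noncoding"):
        return t.coding
    raise ValueError(
        f"cannot resolve coding capacity for transcript {t.transcript_id}: "
        "no override, no sequence, flag unknown"
    )


def classify_lnc(
    transcripts: Sequence[Transcript],
    small_rna_ids: Iterable[str] = (),
    min_lnc_length: int = 200,
) -> list[LncClass]:
    """Assign each transcript to exactly one lncRNA-cascade category.

    Coding transcripts are mRNA.  Noncoding transcripts shorter than
    ``min_lnc_length`` (spliced) are excluded_short; those on the small-RNA
    exclusion list are excluded_smallRNA.  A surviving lncRNA whose genomic
    span overlaps a coding transcript's span on the opposite strand of the
    same chromosome (>= 1 bp) is a lncNAT, otherwise a lincRNA.
    """
    small = set(small_rna_ids)
    for t in transcripts:
        if t.coding == "unknown":
            raise ValueError(
                f"transcript {t.transcript_id} has unresolved coding capacity"
            )
    # index coding spans per (chrom, strand); intervaltree is half-open
    trees: dict[tuple[str, str], IntervalTree] = {}
    for t in transcripts:
        if t.coding == "coding":
            trees.setdefault((t.chrom, t.strand), IntervalTree()).addi(
                t.start, t.end + 1
            )
    out = []
    for t in transcripts:
        if t.coding == "coding":
            cat = "mRNA"
        elif spliced_length(t) < min_lnc_length:
            cat = "excluded_short"
        elif t.transcript_id in small:
            cat = "excluded_smallRNA"
        else:
            opp = "-" if t.strand == "+" else "+"
            tree = trees.get((t.chrom, opp))
            cat = "lncNAT" if tree and tree.overlap(t.start, t.end + 1) else "lincRNA"
        out.append(LncClass(transcript_id=t.transcript_id, category=cat))
    return out
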