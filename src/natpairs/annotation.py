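"""Annotation and expression I/O.

Reads transcript models from GTF (1-based, inclusive, stranded), per-sample
FPKM matrices with their sample metadata, and writes NAT-pair overlap tracks
as BED6.  All genomic coordinates inside the package are 1-based inclusive
(GTF native); the BED boundary is the only place the 0-based half-open
convention appears.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from gffutils.feature import feature_from_line

__all__ = [
    "Transcript",
    "ExpressionMatrix",
    "read_gtf",
    "write_gtf",
    "read_expression",
    "write_pairs_bed",
    "to_bed_interval",
    "from_bed_interval",
]

log = logging.getLogger(__name__)

CODING_STATES = ("coding", "noncoding", "unknown")
CONDITIONS = ("control", "drought")


@dataclass(frozen=True)
class Transcript:
    """A stranded transcript model: genomic span plus its exon chain.

    Coordinates are 1-based inclusive.  ``coding`` records protein-coding
    capacity ("coding", "noncoding", or "unknown" until resolved).
    """

    transcript_id: str
    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str
    exons: tuple[tuple[int, int], ...]
    coding: str = "unknown"

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(
                f"transcript {self.transcript_id}: strand must be '+' or '-', "
                f"got {self.strand!r}"
            )
        if self.start > self.end:
            raise ValueError(
                f"transcript {self.transcript_id}: start {self.start} > end {self.end}"
            )
        if self.coding not in CODING_STATES:
            raise ValueError(
                f"transcript {self.transcript_id}: invalid coding state {self.coding!r}"
            )
        if not self.exons:
            raise ValueError(f"transcript {self.transcript_id}: no exons")
        prev_end = None
        for s, e in self.exons:
            if s > e:
                raise ValueError(
                    f"transcript {self.transcript_id}: exon ({s},{e}) has start > end"
                )
            if s < self.start or e > self.end:
                raise ValueError(
                    f"transcript {self.transcript_id}: exon ({s},{e}) outside span "
                    f"[{self.start},{self.end}]"
                )
            if prev_end is not None and s <= prev_end:
                raise ValueError(
                    f"transcript {self.transcript_id}: exons overlap or are unsorted "
                    f"at ({s},{e})"
                )
            prev_end = e

    @property
    def span_length(self) -> int:
        return self.end - self.start + 1

    @property
    def span(self) -> tuple[int, int]:
        return (self.start, self.end)

    def with_coding(self, coding: str) -> "Transcript":
        return replace(self, coding=coding)


@dataclass
class ExpressionMatrix:
    """Transcript x sample FPKM grid plus sample metadata.

    ``values`` is indexed by transcript_id with one column per sample_id;
    ``meta`` is indexed by sample_id with columns accession, condition,
    replicate.  Absent cells are zeros; negative FPKM is rejected.
    """

    values: pd.DataFrame
    meta: pd.DataFrame

    def __post_init__(self) -> None:
        if (self.values.values < 0).any():
            bad = self.values[(self.values < 0).any(axis=1)].index[0]
            raise ValueError(f"negative FPKM for transcript {bad}")
        missing = [c for c in self.values.columns if c not in self.meta.index]
        if missing:
            raise ValueError(
                f"samples missing from metadata: {', '.join(map(str, missing))}"
            )
        bad_cond = set(self.meta["condition"]) - set(CONDITIONS)
        if bad_cond:
            raise ValueError(f"unknown conditions in metadata: {sorted(bad_cond)}")
        key = self.meta[["accession", "condition", "replicate"]]
        if key.duplicated().any():
            dup = key[key.duplicated()].iloc[0]
            raise ValueError(
                "duplicate (accession, condition, replicate): "
                f"({dup['accession']}, {dup['condition']}, {dup['replicate']})"
            )
        self.values = self.values.fillna(0.0)

    @property
    def accessions(self) -> list[str]:
        seen: list[str] = []
        for a in self.meta["accession"]:
            if a not in seen:
                seen.append(a)
        return seen

    def samples_for(self, accession: str, condition: str) -> list[str]:
        if accession not in set(self.meta["accession"]):
            raise KeyError(f"accession {accession!r} not present in metadata")
        sel = self.meta[
            (self.meta["accession"] == accession)
            & (self.meta["condition"] == condition)
        ]
        return [s for s in sel.index if s in self.values.columns]


def _parse_gtf_line(line: str, lineno: int, path: str):
    if line.count("\t") < 8:
        raise ValueError(
            f"{path}: malformed GTF record at line {lineno}: expected 9 "
            f"tab-separated fields"
        )
    try:
        return feature_from_line(line)
    except Exception as exc:  # gffutils raises assorted parse errors
        raise ValueError(
            f"{path}: malformed GTF record at line {lineno}: {exc}"
        ) from exc


def read_gtf(path) -> list[Transcript]:
    """Read exon features from a GTF file into :class:`Transcript` objects.

    The transcript span is the hull of its exons.  Unstranded records
    (strand ".") are dropped with a single summary warning; a transcript_id
    seen on more than one chromosome or strand is a hard error.  Output is
    sorted by (chrom, start, transcript_id).
    """
    path = Path(path)
    exons: dict[str, list[tuple[int, int]]] = {}
    info: dict[str, tuple[str, str, str]] = {}  # tid -> (gene, chrom, strand)
    unstranded: set[str] = set()
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            feat = _parse_gtf_line(line, lineno, str(path))
            if feat.featuretype != "exon":
                continue
            try:
                tid = feat.attributes["transcript_id"][0]
            except (KeyError, IndexError):
                raise ValueError(
                    f"{path}: exon without transcript_id at line {lineno}"
                ) from None
            gene = feat.attributes.get("gene_id", [tid])[0]
            if feat.strand not in ("+", "-"):
                unstranded.add(tid)
                continue
            if tid in info:
                g, chrom, strand = info[tid]
                if chrom != feat.seqid:
                    raise ValueError(
                        f"{path}: transcript {tid} appears on both {chrom} and "
                        f"{feat.seqid} (line {lineno}): ambiguous identity"
                    )
                if strand != feat.strand:
                    raise ValueError(
                        f"{path}: transcript {tid} has exons on both strands "
                        f"(line {lineno})"
                    )
            else:
                info[tid] = (gene, feat.seqid, feat.strand)
            exons.setdefault(tid, []).append((feat.start, feat.end))
    if unstranded:
        log.warning(
            "excluded %d unstranded ('.') transcript(s) from %s",
            len(unstranded),
            path,
        )
    out = []
    for tid, (gene, chrom, strand) in info.items():
        ex = tuple(sorted(exons[tid]))
        out.append(
            Transcript(
                transcript_id=tid,
                gene_id=gene,
                chrom=chrom,
                start=ex[0][0],
                end=max(e for _, e in ex),
                strand=strand,
                exons=ex,
            )
        )
    out.sort(key=lambda t: (t.chrom, t.start, t.transcript_id))
    return out


def write_gtf(transcripts: Iterable[Transcript], path) -> None:
    """Write one GTF exon line per exon (round-trips through read_gtf)."""
    with open(path, "w") as fh:
        for t in sorted(transcripts, key=lambda t: (t.chrom, t.start, t.transcript_id)):
            for s, e in t.exons:
                fh.write(
                    f"{t.chrom}\tnatpairs\texon\t{s}\t{e}\t.\t{t.strand}\t.\t"
                    f'gene_id "{t.gene_id}"; transcript_id "{t.transcript_id}";\n'
                )


def read_expression(path, meta_path) -> ExpressionMatrix:
    """Read an FPKM TSV (transcripts x samples) and its sample-metadata TSV.

    The metadata file needs columns sample_id, accession, condition,
    replicate; every matrix column must have a metadata row.
    """
    values = pd.read_csv(path, sep="\t", index_col=0)
    values = values.astype(float)
    meta = pd.read_csv(meta_path, sep="\t", dtype={"replicate": int})
    required = {"sample_id", "accession", "condition", "replicate"}
    missing_cols = required - set(meta.columns)
    if missing_cols:
        raise ValueError(
            f"{meta_path}: metadata missing column(s) {sorted(missing_cols)}"
        )
    meta = meta.set_index("sample_id")
    return ExpressionMatrix(values=values, meta=meta)


def to_bed_interval(start: int, end: int) -> tuple[int, int]:
    """1-based inclusive -> 0-based half-open."""
    return start - 1, end


def from_bed_interval(start: int, end: int) -> tuple[int, int]:
    """0-based half-open -> 1-based inclusive."""
    return start + 1, end


def write_pairs_bed(pairs: Sequence, path) -> None:
    """Write the overlap interval of each NAT pair as a BED6 row.

    Name is ``senseID|antisenseID|orientation``; strand column carries the
    sense member's strand.  Rows are sorted by (chrom, start).
    """
    rows = []
    for p in pairs:
        bstart, bend = to_bed_interval(p.overlap_start, p.overlap_end)
        rows.append(
            (p.chrom, bstart, bend, f"{p.sense_id}|{p.antisense_id}|{p.orientation}",
             0, p.sense.strand)
        )
    rows.sort(key=lambda r: (r[0], r[1], r[3]))
    with open(path, "w") as fh:
        for r in rows:
            fh.write("\t".join(map(str, r)) + "\n")
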