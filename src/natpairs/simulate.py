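"""Synthetic annotations and expression matrices with known ground truth.

The generator emulates the study design of the rice drought experiment:
three accessions, control vs drought, three replicates, with sense/antisense
gene models planted at known orientations and fold changes so every pipeline
stage can be checked against planted truth.  Loci are packed into disjoint
genomic slots, which guarantees that the only opposite-strand overlaps in
the output are the planted ones.  Replicate noise is log-normal: Normal on
the log2-FPKM scale, exponentiated.

Also ships the ten stress-linked coding-noncoding pair coordinates printed
in the study as a machine-readable fixture (:func:`table1_fixture`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .annotation import ExpressionMatrix, Transcript, write_gtf

__all__ = [
    "SimSpec",
    "PlantedPair",
    "GroundTruth",
    "SimResult",
    "simulate",
    "table1_fixture",
    "table1_transcripts",
]

RESPONSE_CLASSES = ("concordant_up", "concordant_down", "discordant", "null")


@dataclass
class SimSpec:
    """Parameters of one synthetic study.

    Defaults reproduce the study conditions the pipeline is meant for:
    3 accessions x 2 conditions x 3 replicates, ~1000 transcripts, planted
    8-fold (|log2fc| = 3) drought effects with log2-scale replicate noise of
    0.25.
    """

    seed: int = 0
    n_chromosomes: int = 4
    chrom_length: int = 2_000_000
    n_coding: int = 600
    n_lnc: int = 400
    orientation_mix: Mapping[str, float] = field(
        default_factory=lambda: {
            "enclosed": 0.30,
            "divergent": 0.25,
            "convergent": 0.25,
            "none": 0.20,
        }
    )
    pair_overlap_range: tuple[int, int] = (25, 2000)
    accessions: tuple[str, ...] = ("Nip", "BJ89", "BJ278")
    n_replicates: int = 3
    planted_effects: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "concordant_up": (3.0, 3.0),
            "concordant_down": (-3.0, -3.0),
            "discordant": (3.0, -3.0),
            "null": (0.0, 0.0),
        }
    )
    response_mix: Mapping[str, float] = field(
        default_factory=lambda: {
            "concordant_up": 0.3,
            "concordant_down": 0.3,
            "discordant": 0.3,
            "null": 0.1,
        }
    )
    accession_response_prob: float = 0.7
    noise_sd: float = 0.25
    baseline_logfpkm_range: tuple[float, float] = (2.0, 7.0)

    def __post_init__(self) -> None:
        for name, mix in (("orientation_mix", self.orientation_mix),
                          ("response_mix", self.response_mix)):
            total = sum(mix.values())
            if not math.isclose(total, 1.0, abs_tol=1e-9):
                raise ValueError(f"{name} probabilities sum to {total}, not 1")
        lo, hi = self.pair_overlap_range
        if not (1 <= lo <= hi <= self.chrom_length):
            raise ValueError(
                f"pair_overlap_range {self.pair_overlap_range} outside "
                f"[1, {self.chrom_length}]"
            )


@dataclass(frozen=True)
class PlantedPair:
    sense_id: str
    antisense_id: str
    orientation: str
    coding_class: str
    #: accession -> planted response status (null accessions omitted)
    response: Mapping[str, str]
    response_class: str


@dataclass
class GroundTruth:
    #: transcript_id -> planted category (mRNA / lincRNA / lncNAT)
    category: dict[str, str]
    pairs: list[PlantedPair]

    def pair_by_key(self) -> dict[tuple[str, str], PlantedPair]:
        return {(p.sense_id, p.antisense_id): p for p in self.pairs}


@dataclass
class SimResult:
    spec: SimSpec
    transcripts: list[Transcript]
    expression: ExpressionMatrix
    coding: dict[str, str]
    truth: GroundTruth

    def to_dir(self, outdir) -> None:
        """Write sim.gtf, fpkm.tsv, meta.tsv, coding.tsv and truth.tsv."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_gtf(self.transcripts, outdir / "sim.gtf")
        self.expression.values.to_csv(outdir / "fpkm.tsv", sep="\t")
        self.expression.meta.to_csv(outdir / "meta.tsv", sep="\t")
        with open(outdir / "coding.tsv", "w") as fh:
            for tid in sorted(self.coding):
                fh.write(f"{tid}\t{self.coding[tid]}\n")
        rows = []
        for p in self.truth.pairs:
            for acc, status in sorted(p.response.items()):
                rows.append(
                    f"{p.sense_id}\t{p.antisense_id}\t{p.orientation}\t"
                    f"{p.coding_class}\t{acc}\t{status}"
                )
        with open(outdir / "truth.tsv", "w") as fh:
            fh.write("sense_id\tantisense_id\torientation\tcoding_class\t"
                     "accession\tstatus\n")
            for r in rows:
                fh.write(r + "\n")


def _draw_orientation(rng: np.random.Generator, mix: Mapping[str, float]) -> str:
    names = sorted(mix)
    return str(rng.choice(names, p=[mix[n] for n in names]))


def _single_locus(rng: np.random.Generator, tid: str, gene: str, coding: bool):
    """Span/exon layout of a standalone transcript, relative to 0."""
    n_ex = int(rng.integers(1, 4))
    exon_lens = rng.integers(200, 701, n_ex)
    intron_lens = rng.integers(50, 201, n_ex - 1) if n_ex > 1 else []
    exons = []
    pos = 0
    for i, el in enumerate(exon_lens):
        exons.append((pos, pos + int(el) - 1))
        pos = exons[-1][1] + 1
        if i < n_ex - 1:
            pos += int(intron_lens[i])
    strand = "+" if rng.random() < 0.5 else "-"
    return {
        "kind": "single",
        "tid": tid,
        "gene": gene,
        "strand": strand,
        "coding": "coding" if coding else "noncoding",
        "exons": exons,
        "width": exons[-1][1] + 1,
    }


def _pair_locus(
    rng: np.random.Generator,
    spec: SimSpec,
    ids: tuple[str, str],
    genes: tuple[str, str],
    codings: tuple[str, str],
    orientation: str,
):
    """Plus/minus spans (relative to 0) satisfying the orientation exactly."""
    lo, hi = spec.pair_overlap_range
    ov = int(rng.integers(lo, hi + 1))

    def member_len(coding: str) -> int:
        extra = int(rng.integers(1, 400))
        floor = 200 if coding == "noncoding" else 1
        return max(ov + extra, floor)

    if orientation == "enclosed":
        # inner span length == overlap; a noncoding member must clear the
        # 200 nt lncRNA floor, so it takes the outer span for short overlaps
        if ov < 200 and codings == ("noncoding", "coding"):
            plus_is_outer = True
        elif ov < 200 and codings == ("coding", "noncoding"):
            plus_is_outer = False
        else:
            plus_is_outer = rng.random() < 0.5
        pad_l = int(rng.integers(1, 400))
        pad_r = int(rng.integers(1, 400))
        outer_len = ov + pad_l + pad_r
        outer_coding = codings[0] if plus_is_outer else codings[1]
        if outer_coding == "noncoding" and outer_len < 200:
            pad_r += 200 - outer_len
        outer = (0, ov + pad_l + pad_r - 1)
        inner = (pad_l, pad_l + ov - 1)
        spans = (outer, inner) if plus_is_outer else (inner, outer)
    elif orientation == "divergent":
        # minus member M starts left: m1 < p1 <= m2 < p2
        m_len = member_len(codings[1])
        p_len = member_len(codings[0])
        m = (0, m_len - 1)
        p = (m[1] - ov + 1, m[1] - ov + p_len)
        spans = (p, m)
    elif orientation == "convergent":
        # plus member P starts left: p1 < m1 <= p2 < m2
        p_len = member_len(codings[0])
        m_len = member_len(codings[1])
        p = (0, p_len - 1)
        m = (p[1] - ov + 1, p[1] - ov + m_len)
        spans = (p, m)
    else:  # pragma: no cover
        raise ValueError(f"unknown orientation {orientation!r}")

    shift = -min(s[0] for s in spans)
    spans = tuple((s[0] + shift, s[1] + shift) for s in spans)
    width = max(s[1] for s in spans) + 1
    return {
        "kind": "pair",
        "ids": ids,  # (plus member, minus member)
        "genes": genes,
        "codings": codings,
        "spans": spans,
        "orientation": orientation,
        "overlap": ov,
        "width": width,
    }


def simulate(spec: SimSpec) -> SimResult:
    """Generate a synthetic annotation + expression matrix with ground truth.

    Deterministic for a fixed seed.  Planted pairs satisfy their orientation
    definition by construction; 'none' transcripts are placed in disjoint
    slots and therefore enter no pair.
    """
    rng = np.random.default_rng(spec.seed)

    lnc_orients = [
        _draw_orientation(rng, spec.orientation_mix) for _ in range(spec.n_lnc)
    ]
    n_paired_lnc = sum(o != "none" for o in lnc_orients)
    if n_paired_lnc > spec.n_coding:
        raise ValueError(
            f"{n_paired_lnc} lncRNAs need coding partners but only "
            f"{spec.n_coding} coding transcripts requested"
        )
    n_free_coding = spec.n_coding - n_paired_lnc
    coding_orients = [
        _draw_orientation(rng, spec.orientation_mix) for _ in range(n_free_coding)
    ]

    loci = []
    coding_i = lnc_i = 0

    def next_coding_id():
        nonlocal coding_i
        coding_i += 1
        return f"COD{coding_i:05d}.1", f"GCOD{coding_i:05d}"

    def next_lnc_id():
        nonlocal lnc_i
        lnc_i += 1
        return f"LNC{lnc_i:05d}.1", f"GLNC{lnc_i:05d}"

    for orient in lnc_orients:
        ltid, lgene = next_lnc_id()
        if orient == "none":
            loci.append(_single_locus(rng, ltid, lgene, coding=False))
        else:
            ctid, cgene = next_coding_id()
            coding_is_plus = rng.random() < 0.5
            if coding_is_plus:
                ids, genes, codings = (ctid, ltid), (cgene, lgene), ("coding", "noncoding")
            else:
                ids, genes, codings = (ltid, ctid), (lgene, cgene), ("noncoding", "coding")
            loci.append(_pair_locus(rng, spec, ids, genes, codings, orient))

    pending: Optional[tuple[str, str, str]] = None  # (tid, gene, orientation)
    for orient in coding_orients:
        ctid, cgene = next_coding_id()
        if orient == "none":
            loci.append(_single_locus(rng, ctid, cgene, coding=True))
        elif pending is None:
            pending = (ctid, cgene, orient)
        else:
            ptid, pgene, porient = pending
            pending = None
            loci.append(
                _pair_locus(
                    rng, spec, (ptid, ctid), (pgene, cgene),
                    ("coding", "coding"), porient,
                )
            )
    if pending is not None:
        loci.append(_single_locus(rng, pending[0], pending[1], coding=True))

    # pack loci into disjoint slots, cycling chromosomes
    gap = 500
    cursors = {f"chr{i + 1:02d}": 1 for i in range(spec.n_chromosomes)}
    chrom_names = list(cursors)
    transcripts: list[Transcript] = []
    truth_cat: dict[str, str] = {}
    coding_flags: dict[str, str] = {}
    planted: list[PlantedPair] = []
    chrom_idx = 0
    for locus in loci:
        placed = False
        for _ in range(spec.n_chromosomes):
            chrom = chrom_names[chrom_idx % spec.n_chromosomes]
            chrom_idx += 1
            base = cursors[chrom]
            if base + locus["width"] + gap <= spec.chrom_length:
                cursors[chrom] = base + locus["width"] + gap
                placed = True
                break
        if not placed:
            raise ValueError(
                "could not place all loci: increase chrom_length or "
                "n_chromosomes, or reduce transcript counts"
            )
        if locus["kind"] == "single":
            exons = tuple((base + s, base + e) for s, e in locus["exons"])
            t = Transcript(
                transcript_id=locus["tid"],
                gene_id=locus["gene"],
                chrom=chrom,
                start=exons[0][0],
                end=exons[-1][1],
                strand=locus["strand"],
                exons=exons,
                coding=locus["coding"],
            )
            transcripts.append(t)
            coding_flags[t.transcript_id] = locus["coding"]
            truth_cat[t.transcript_id] = (
                "mRNA" if locus["coding"] == "coding" else "lincRNA"
            )
        else:
            members = []
            for (tid, gene, coding, span, strand) in zip(
                locus["ids"], locus["genes"], locus["codings"],
                locus["spans"], ("+", "-"),
            ):
                t = Transcript(
                    transcript_id=tid,
                    gene_id=gene,
                    chrom=chrom,
                    start=base + span[0],
                    end=base + span[1],
                    strand=strand,
                    exons=((base + span[0], base + span[1]),),
                    coding=coding,
                )
                members.append(t)
                coding_flags[tid] = coding
                truth_cat[tid] = "mRNA" if coding == "coding" else "lncNAT"
            codings = locus["codings"]
            if codings == ("coding", "coding"):
                cclass, sense, anti = "coding_coding", members[0], members[1]
            else:
                cclass = "coding_noncoding"
                sense = members[0] if codings[0] == "coding" else members[1]
                anti = members[1] if sense is members[0] else members[0]
            rclass = str(
                rng.choice(sorted(spec.response_mix),
                           p=[spec.response_mix[k] for k in sorted(spec.response_mix)])
            )
            designated = [
                a for a in spec.accessions
                if rng.random() < spec.accession_response_prob
            ]
            if rclass != "null" and not designated:
                designated = [
                    spec.accessions[int(rng.integers(len(spec.accessions)))]
                ]
            response = {a: rclass for a in designated} if rclass != "null" else {}
            planted.append(
                PlantedPair(
                    sense_id=sense.transcript_id,
                    antisense_id=anti.transcript_id,
                    orientation=locus["orientation"],
                    coding_class=cclass,
                    response=response,
                    response_class=rclass,
                )
            )
            transcripts.extend(members)

    transcripts.sort(key=lambda t: (t.chrom, t.start, t.transcript_id))
    tids = [t.transcript_id for t in transcripts]
    tid_idx = {tid: i for i, tid in enumerate(tids)}

    # planted log2 effects per (transcript, accession)
    effects = np.zeros((len(tids), len(spec.accessions)))
    acc_idx = {a: j for j, a in enumerate(spec.accessions)}
    for p in planted:
        s_eff, a_eff = spec.planted_effects[p.response_class]
        for acc in p.response:
            effects[tid_idx[p.sense_id], acc_idx[acc]] += s_eff
            effects[tid_idx[p.antisense_id], acc_idx[acc]] += a_eff

    baseline = rng.uniform(*spec.baseline_logfpkm_range, size=len(tids))
    sample_ids, meta_rows, cols = [], [], []
    for acc in spec.accessions:
        for cond in ("control", "drought"):
            for rep in range(1, spec.n_replicates + 1):
                sid = f"{acc}_{cond}_{rep}"
                sample_ids.append(sid)
                meta_rows.append(
                    {"sample_id": sid, "accession": acc, "condition": cond,
                     "replicate": rep}
                )
                mean = baseline.copy()
                if cond == "drought":
                    mean = mean + effects[:, acc_idx[acc]]
                cols.append(mean)
    noise = rng.normal(0.0, spec.noise_sd, size=(len(sample_ids), len(tids)))
    values = np.power(2.0, np.asarray(cols) + noise).T
    expr = ExpressionMatrix(
        values=pd.DataFrame(
            values, index=pd.Index(tids, name="transcript_id"), columns=sample_ids
        ),
        meta=pd.DataFrame(meta_rows).set_index("sample_id"),
    )
    return SimResult(
        spec=spec,
        transcripts=transcripts,
        expression=expr,
        coding=coding_flags,
        truth=GroundTruth(category=truth_cat, pairs=planted),
    )


# --- the printed ten stress-linked coding-noncoding pairs --------------------

_TABLE1_ROWS = [
    ("chr01", "MSTRG.1295.1", 8546015, 8546972,
     "Os01t0256500-02", 8546065, 8546869, "GO:0006950", ("BJ89",)),
    ("chr03", "MSTRG.12385.1", 16407687, 16410061,
     "Os03t0402800-01", 16407699, 16410007, "GO:0009753", ("BJ89", "BJ278")),
    ("chr03", "MSTRG.12385.1", 16407687, 16410061,
     "Os03t0402800-02", 16407695, 16408985, "GO:0009753", ("BJ89",)),
    ("chr03", "Os03t0161900-01", 3342277, 3344547,
     "MSTRG.10570.1", 3342143, 3344510, "GO:0006950", ("BJ89",)),
    ("chr03", "Os03t0161900-02", 3342254, 3344542,
     "MSTRG.10570.1", 3342143, 3344510, "GO:0006950", ("BJ89",)),
    ("chr04", "Os04t0497700-01", 24889983, 24891470,
     "MSTRG.16704.1", 24889504, 24891481, "GO:0055114", ("BJ89",)),
    ("chr07", "Os07t0615200-01", 25348060, 25350242,
     "MSTRG.27311.1", 25348061, 25350279, "GO:0009867", ("BJ89",)),
    ("chr08", "Os08t0504700-01", 24953937, 24954919,
     "MSTRG.30183.1", 24953534, 24955156, "GO:0006950", ("Nip", "BJ89", "BJ278")),
    ("chr09", "MSTRG.30767.1", 656756, 658373,
     "Os09t0106700-01", 656788, 658373, "GO:0006950", ("BJ89",)),
    ("chr09", "MSTRG.31075.1", 5538425, 5540535,
     "Os09t0273600-00", 5538561, 5539063, "GO:0006950", ("BJ89",)),
]


def _gene_of(tid: str) -> str:
    if tid.startswith("MSTRG."):
        return tid.rsplit(".", 1)[0]
    return tid.split("-")[0]


def table1_fixture() -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """The ten printed stress-linked pairs as three tables.

    Returns (pairs, gene2go, membership): the pair coordinates with their
    GO term, the sense-gene GO annotations, and one row per (pair,
    accession) in which the pair was found.  Byte-stable across calls.
    """
    pairs = pd.DataFrame(
        [r[:8] for r in _TABLE1_ROWS],
        columns=["chrom", "sense_id", "sense_start", "sense_end",
                 "antisense_id", "antisense_start", "antisense_end", "go_id"],
    )
    gene2go = (
        pd.DataFrame(
            {"gene_id": [_gene_of(r[1]) for r in _TABLE1_ROWS],
             "go_id": [r[7] for r in _TABLE1_ROWS]}
        )
        .drop_duplicates()
        .reset_index(drop=True)
    )
    membership = pd.DataFrame(
        [
            {"sense_id": r[1], "antisense_id": r[4], "accession": acc}
            for r in _TABLE1_ROWS
            for acc in r[8]
        ]
    )
    return pairs, gene2go, membership


def table1_transcripts() -> list[Transcript]:
    """Toy annotation of the printed pairs: coding sense on +, lncRNA on -."""
    seen: dict[str, Transcript] = {}
    for r in _TABLE1_ROWS:
        chrom, sid, ss, se, aid, as_, ae = r[:7]
        for tid, start, end, strand, coding in (
            (sid, ss, se, "+", "coding"),
            (aid, as_, ae, "-", "noncoding"),
        ):
            if tid not in seen:
                seen[tid] = Transcript(
                    transcript_id=tid,
                    gene_id=_gene_of(tid),
                    chrom=chrom,
                    start=start,
                    end=end,
                    strand=strand,
                    exons=((start, end),),
                    coding=coding,
                )
    return sorted(seen.values(), key=lambda t: (t.chrom, t.start, t.transcript_id))
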