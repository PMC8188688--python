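"""Model-style front end over the NAT-pair pipeline.

:class:`NATPairAnalysis` is constructed from an annotation (plus optional
expression data and GO annotations); :meth:`NATPairAnalysis.fit` runs the
classification cascade, the pair scan and, when expression is available,
the per-accession drought-response analysis, returning a
:class:`NATPairResults` that carries the tables and a ``summary()``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .annotation import ExpressionMatrix, Transcript, read_expression, read_gtf
from .classify import assign_coding, classify_lnc
from .pairs import NATPair, pairs_to_frame, scan_pairs
from .response import (
    STRESS_TERMS,
    VennPartition,
    call_de,
    classify_pairs,
    go_link,
    venn_partition,
)

__all__ = ["NATPairAnalysis", "NATPairResults"]


class NATPairAnalysis:
    """Strand-aware NAT-pair analysis of one annotated transcriptome.

    Parameters
    ----------
    transcripts
        Stranded transcript models (e.g. from :func:`natpairs.read_gtf`).
    expression
        Optional FPKM matrix with accession/condition/replicate metadata;
        required for the drought-response stage.
    coding_overrides
        transcript_id -> "coding"/"noncoding" flags; they take precedence
        over any flag already on the transcript.
    small_rna_ids
        Transcripts to exclude as small noncoding RNAs (e.g. Rfam hits).
    gene2go, stress_terms
        Gene-level GO annotations and the stress-term subset used to link
        responsive pairs to drought biology.
    """

    def __init__(
        self,
        transcripts: Sequence[Transcript],
        expression: Optional[ExpressionMatrix] = None,
        *,
        coding_overrides: Optional[Mapping[str, str]] = None,
        small_rna_ids: Iterable[str] = (),
        sequences: Optional[Mapping[str, str]] = None,
        gene2go: Optional[Mapping[str, Iterable[str]]] = None,
        stress_terms: Iterable[str] = STRESS_TERMS,
        min_orf_codons: int = 100,
        min_lnc_length: int = 200,
    ) -> None:
        seqs = sequences or {}
        self.transcripts = [
            t.with_coding(
                assign_coding(
                    t,
                    overrides=coding_overrides,
                    min_orf_codons=min_orf_codons,
                    sequence=seqs.get(t.transcript_id),
                )
            )
            for t in transcripts
        ]
        self.expression = expression
        self.small_rna_ids = set(small_rna_ids)
        self.gene2go = dict(gene2go or {})
        self.stress_terms = set(stress_terms)
        self.min_lnc_length = min_lnc_length

    @classmethod
    def from_files(
        cls,
        gtf_path,
        expression_path=None,
        meta_path=None,
        coding_path=None,
        small_rna_path=None,
        gene2go_path=None,
        **kwargs,
    ) -> "NATPairAnalysis":
        """Build the model from the standard on-disk formats."""
        transcripts = read_gtf(gtf_path)
        expression = None
        if expression_path is not None:
            if meta_path is None:
                raise ValueError("expression_path requires meta_path")
            expression = read_expression(expression_path, meta_path)
        overrides = None
        if coding_path is not None:
            overrides = {}
            with open(coding_path) as fh:
                for line in fh:
                    if line.strip():
                        tid, flag = line.rstrip("\n").split("\t")[:2]
                        overrides[tid] = flag
        small = set()
        if small_rna_path is not None:
            with open(small_rna_path) as fh:
                small = {line.strip() for line in fh if line.strip()}
        gene2go: dict[str, set[str]] = {}
        if gene2go_path is not None:
            with open(gene2go_path) as fh:
                for line in fh:
                    if line.strip():
                        gene, go = line.rstrip("\n").split("\t")[:2]
                        gene2go.setdefault(gene, set()).add(go)
        return cls(
            transcripts,
            expression,
            coding_overrides=overrides,
            small_rna_ids=small,
            gene2go=gene2go,
            **kwargs,
        )

    def fit(
        self,
        min_overlap: int = 25,
        overlap_mode: str = "span",
        fc_threshold: float = 2.0,
        hdeg_fc: float = 4.0,
        q_threshold: float = 0.01,
        de_method: str = "moderated",
    ) -> "NATPairResults":
        """Run the pipeline and return the results object."""
        lnc_classes = classify_lnc(
            self.transcripts,
            small_rna_ids=self.small_rna_ids,
            min_lnc_length=self.min_lnc_length,
        )
        pairs = scan_pairs(
            self.transcripts, min_overlap=min_overlap, overlap_mode=overlap_mode
        )
        de: dict[str, pd.DataFrame] = {}
        responses = None
        venn_responsive = None
        venn_discordant = None
        if self.expression is not None:
            for acc in self.expression.accessions:
                de[acc] = call_de(
                    self.expression,
                    acc,
                    fc_threshold=fc_threshold,
                    q_threshold=q_threshold,
                    hdeg_fc=hdeg_fc,
                    method=de_method,
                )
            responses = classify_pairs(pairs, de)
            if len(de) == 3:
                accs = list(de)
                resp = responses[responses["status"] != "not_responsive"]
                members = {
                    a: set(
                        map(
                            tuple,
                            resp[resp["accession"] == a][
                                ["sense_id", "antisense_id"]
                            ].itertuples(index=False),
                        )
                    )
                    for a in accs
                }
                venn_responsive = venn_partition(members, accs)
                disc = responses[responses["status"] == "discordant"]
                members_d = {
                    a: set(
                        map(
                            tuple,
                            disc[disc["accession"] == a][
                                ["sense_id", "antisense_id"]
                            ].itertuples(index=False),
                        )
                    )
                    for a in accs
                }
                venn_discordant = venn_partition(members_d, accs)
        links = None
        if self.gene2go and responses is not None:
            resp = responses[responses["status"] != "not_responsive"]
            by_pair: dict[tuple[str, str], set[str]] = {}
            for row in resp.itertuples(index=False):
                by_pair.setdefault((row.sense_id, row.antisense_id), set()).add(
                    row.accession
                )
            links = go_link(
                pairs, self.gene2go, self.stress_terms, responsive_accessions=by_pair
            )
        return NATPairResults(
            model=self,
            lnc_classes=pd.DataFrame(
                [(c.transcript_id, c.category) for c in lnc_classes],
                columns=["transcript_id", "category"],
            ),
            pairs=pairs,
            de=de,
            pair_responses=responses,
            venn_responsive=venn_responsive,
            venn_discordant=venn_discordant,
            stress_links=links,
        )


@dataclass
class NATPairResults:
    """Fitted output of :class:`NATPairAnalysis`."""

    model: NATPairAnalysis
    lnc_classes: pd.DataFrame
    pairs: list[NATPair]
    de: dict[str, pd.DataFrame]
    pair_responses: Optional[pd.DataFrame]
    venn_responsive: Optional[VennPartition]
    venn_discordant: Optional[VennPartition]
    stress_links: Optional[list] = None

    @property
    def pairs_frame(self) -> pd.DataFrame:
        return pairs_to_frame(self.pairs)

    def summary(self) -> str:
        """Plain-text overview of the fitted catalogue."""
        lines = ["NAT-pair analysis summary", "=" * 25]
        counts = self.lnc_classes["category"].value_counts()
        lines.append("Transcript categories:")
        for cat in ("mRNA", "lincRNA", "lncNAT", "excluded_smallRNA", "excluded_short"):
            if cat in counts:
                lines.append(f"  {cat:18s} {counts[cat]:6d}")
        lines.append(f"NAT pairs (total): {len(self.pairs)}")
        pf = self.pairs_frame
        if len(pf):
            for col in ("orientation", "coding_class"):
                lines.append(f"  by {col}:")
                for k, v in pf[col].value_counts().items():
                    frac = 100.0 * v / len(pf)
                    lines.append(f"    {k:20s} {v:6d} ({frac:.2f}%)")
        if self.pair_responses is not None:
            lines.append("Drought-responsive pairs per accession:")
            resp = self.pair_responses[
                self.pair_responses["status"] != "not_responsive"
            ]
            for acc, grp in resp.groupby("accession", sort=False):
                by = grp["status"].value_counts().to_dict()
                total = len(grp)
                lines.append(f"  {acc:8s} {total:5d}  {by}")
            if self.venn_responsive is not None:
                lines.append(
                    f"Responsive-pair union across accessions: "
                    f"{self.venn_responsive.union}"
                )
        if self.stress_links:
            lines.append(f"Stress-GO-linked coding-noncoding pairs: "
                         f"{len({l.pair.key for l in self.stress_links})}")
        return "\n".join(lines)

    def plot_orientation_counts(self, ax=None):
        """Bar plot of pair counts per orientation class."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        counts = self.pairs_frame["orientation"].value_counts()
        ax.bar(counts.index, counts.values)
        ax.set_ylabel("NAT pairs")
        ax.set_xlabel("orientation")
        return ax
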