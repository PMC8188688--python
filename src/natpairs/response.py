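"""Drought-response analysis of transcripts and NAT pairs.

Differential expression between drought and control is called per accession
with Welch's two-sample test on log2(FPKM + 1) across replicates and a
Benjamini-Hochberg FDR across all transcripts of that accession.  A
transcript is a DEG at fold change >= 2 and q <= 0.01, and an HDEG at fold
change >= 4 (fold change is the pseudocounted mean-FPKM ratio, in either
direction).  A NAT pair is drought-responsive in an accession when both
members are DEGs there: concordant when they move together, discordant when
they move in opposite directions.  Findings are partitioned across the
three accessions with a seven-region Venn decomposition, and sense partners
are linked to stress-related GO terms via a flat hypergeometric enrichment.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import digamma, polygamma
from statsmodels.stats.multitest import multipletests

from .annotation import ExpressionMatrix
from .pairs import NATPair

__all__ = [
    "call_de",
    "classify_pair_response",
    "classify_pairs",
    "PairResponse",
    "VennPartition",
    "venn_partition",
    "expressed_in",
    "GoLink",
    "go_link",
    "enrich_hypergeom",
    "STRESS_TERMS",
]

#: stress-related GO terms linked to drought response in the rice study
STRESS_TERMS = frozenset(
    {"GO:0006950", "GO:0009753", "GO:0055114", "GO:0009867"}
)

RESPONSE_STATUSES = ("not_responsive", "discordant", "concordant_up", "concordant_down")


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y by Newton iteration (monotone decreasing)."""
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = float(polygamma(1, x))
        step = tri * (1.0 - tri / y) / float(polygamma(2, x))
        x += step
        if abs(step) < 1e-10 * x:
            break
    return x


def _squeeze_var(s2: np.ndarray, df: float) -> tuple[np.ndarray, float]:
    """Empirical-Bayes shrinkage of per-transcript variances.

    Models the sample variances as s0^2 * F(df, d0) and fits (s0^2, d0) by
    matching moments of log s2, then returns the posterior variances
    (d0*s0^2 + df*s2) / (d0 + df) and the prior df d0 (inf when the
    variances are consistent with a single common value).
    """
    ok = s2 > 0
    if ok.sum() < 2:
        return s2.copy(), 0.0
    z = np.log(s2[ok])
    e = z - digamma(df / 2.0) + np.log(df / 2.0)
    evar = e.var(ddof=1) - float(polygamma(1, df / 2.0))
    if evar > 0:
        d0 = 2.0 * _trigamma_inverse(evar)
        s0_2 = np.exp(e.mean() + digamma(d0 / 2.0) - np.log(d0 / 2.0))
        post = (d0 * s0_2 + df * s2) / (d0 + df)
        return post, d0
    s0_2 = np.exp(e.mean())
    return np.full_like(s2, s0_2), np.inf


def _de_pvalues(ld: np.ndarray, lc: np.ndarray, method: str) -> np.ndarray:
    """Two-sample p-values on log2 expression, per transcript (rows)."""
    if method == "welch":
        with np.errstate(divide="ignore", invalid="ignore"):
            _, p = stats.ttest_ind(ld, lc, axis=1, equal_var=False)
        # zero within-group variance: no evidence if means agree, else certain
        nan = np.isnan(p)
        if nan.any():
            same = np.isclose(ld.mean(axis=1), lc.mean(axis=1))
            p = np.where(nan, np.where(same, 1.0, 0.0), p)
        return p
    if method != "moderated":
        raise ValueError(f"unknown DE method {method!r}")
    n1, n2 = ld.shape[1], lc.shape[1]
    df = n1 + n2 - 2
    rss = ((ld - ld.mean(axis=1, keepdims=True)) ** 2).sum(axis=1) + (
        (lc - lc.mean(axis=1, keepdims=True)) ** 2
    ).sum(axis=1)
    s2 = rss / df
    s2_post, d0 = _squeeze_var(s2, df)
    diff = ld.mean(axis=1) - lc.mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = diff / np.sqrt(s2_post * (1.0 / n1 + 1.0 / n2))
    t = np.where(np.isnan(t), 0.0, t)  # 0/0: no difference, no evidence
    df_total = df + d0
    if np.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), df_total)
    return np.where(np.isinf(t), 0.0, p)


def call_de(
    expr: ExpressionMatrix,
    accession: str,
    fc_threshold: float = 2.0,
    q_threshold: float = 0.01,
    hdeg_fc: float = 4.0,
    pseudocount: float = 1.0,
    method: str = "moderated",
) -> pd.DataFrame:
    """Per-transcript differential-expression calls for one accession.

    Returns a frame indexed by transcript_id with columns log2fc, p, q,
    call ('none'/'DEG'/'HDEG') and direction ('up'/'down'/'none').  Fold
    change is (mean drought FPKM + eps) / (mean control FPKM + eps).

    ``method`` selects the replicate-level test on log2(FPKM + eps):
    "moderated" (default) is a moderated t-statistic with empirical-Bayes
    variance shrinkage across transcripts — the appropriate choice at 2-3
    replicates per condition, where raw per-transcript variances are too
    noisy; "welch" is the plain unequal-variance t-test.  q is BH-adjusted
    across all transcripts tested for this accession.
    """
    c_cols = expr.samples_for(accession, "control")
    d_cols = expr.samples_for(accession, "drought")
    for name, cols in (("control", c_cols), ("drought", d_cols)):
        if len(cols) < 2:
            raise ValueError(
                f"accession {accession}: need >=2 {name} replicates, found {len(cols)}"
            )
    eps = pseudocount
    ctrl = expr.values[c_cols].to_numpy(float)
    drt = expr.values[d_cols].to_numpy(float)
    ratio = (drt.mean(axis=1) + eps) / (ctrl.mean(axis=1) + eps)
    log2fc = np.log2(ratio)
    lc = np.log2(ctrl + eps)
    ld = np.log2(drt + eps)
    p = _de_pvalues(ld, lc, method)
    q = multipletests(p, method="fdr_bh")[1]
    fc_mag = np.maximum(ratio, 1.0 / ratio)
    sig = q <= q_threshold
    deg = sig & (fc_mag >= fc_threshold)
    hdeg = sig & (fc_mag >= hdeg_fc)
    call = np.where(hdeg, "HDEG", np.where(deg, "DEG", "none"))
    direction = np.where(deg, np.where(log2fc > 0, "up", "down"), "none")
    return pd.DataFrame(
        {
            "accession": accession,
            "log2fc": log2fc,
            "p": p,
            "q": q,
            "call": call,
            "direction": direction,
        },
        index=pd.Index(expr.values.index, name="transcript_id"),
    )


@dataclass(frozen=True)
class PairResponse:
    pair: NATPair
    accession: str
    status: str

    def __post_init__(self) -> None:
        if self.status not in RESPONSE_STATUSES:
            raise ValueError(f"unknown pair response status {self.status!r}")


def classify_pair_response(
    pair: NATPair,
    de: Mapping[str, pd.DataFrame],
    accession: str,
) -> PairResponse:
    """Drought-response status of one NAT pair in one accession.

    Both members DEGs moving the same way -> concordant_up/_down; opposite
    ways -> discordant; anything less -> not_responsive.
    """
    if accession not in de:
        raise KeyError(f"no differential-expression results for accession {accession}")
    table = de[accession]
    for tid in (pair.sense_id, pair.antisense_id):
        if tid not in table.index:
            raise KeyError(
                f"no differential-expression result for transcript {tid} "
                f"in accession {accession}"
            )
    s = table.loc[pair.sense_id]
    a = table.loc[pair.antisense_id]
    if s["call"] == "none" or a["call"] == "none":
        status = "not_responsive"
    elif s["direction"] == a["direction"]:
        status = "concordant_up" if s["direction"] == "up" else "concordant_down"
    else:
        status = "discordant"
    return PairResponse(pair=pair, accession=accession, status=status)


def classify_pairs(
    pairs: Sequence[NATPair],
    de: Mapping[str, pd.DataFrame],
) -> pd.DataFrame:
    """Response status of every pair in every accession, one row each."""
    rows = []
    for p in pairs:
        for acc in de:
            r = classify_pair_response(p, de, acc)
            rows.append(
                {
                    "chrom": p.chrom,
                    "sense_id": p.sense_id,
                    "antisense_id": p.antisense_id,
                    "coding_class": p.coding_class,
                    "accession": acc,
                    "status": r.status,
                }
            )
    return pd.DataFrame(
        rows,
        columns=["chrom", "sense_id", "antisense_id", "coding_class",
                 "accession", "status"],
    )


@dataclass(frozen=True)
class VennPartition:
    """Seven-region decomposition of a membership property over 3 sets.

    ``region_counts`` is keyed by tuples of accession names in the fixed
    reporting order: three singles, three pairwise-only regions, and the
    triple intersection.
    """

    accessions: tuple[str, str, str]
    region_counts: Mapping[tuple[str, ...], int]

    @property
    def union(self) -> int:
        return sum(self.region_counts.values())

    def marginal(self, accession: str) -> int:
        if accession not in self.accessions:
            raise KeyError(f"unknown accession {accession!r}")
        return sum(
            n for region, n in self.region_counts.items() if accession in region
        )

    def only(self, *accessions: str) -> int:
        return self.region_counts[tuple(accessions)]


def venn_partition(
    membership: Mapping[str, Iterable],
    accessions: Sequence[str],
) -> VennPartition:
    """Exact 7-region Venn counts of item membership across three accessions."""
    accs = tuple(accessions)
    if len(accs) != 3:
        raise ValueError(f"venn_partition needs exactly 3 accessions, got {len(accs)}")
    unknown = set(membership) - set(accs)
    if unknown:
        raise ValueError(f"membership given for unknown accession(s): {sorted(unknown)}")
    sets = {a: set(membership.get(a, ())) for a in accs}
    a, b, c = accs
    regions: dict[tuple[str, ...], int] = {}
    universe = sets[a] | sets[b] | sets[c]
    combos = [(a,), (b,), (c,), (a, b), (a, c), (b, c), (a, b, c)]
    for combo in combos:
        inside = set(universe)
        for acc in combo:
            inside &= sets[acc]
        for acc in accs:
            if acc not in combo:
                inside -= sets[acc]
        regions[combo] = len(inside)
    return VennPartition(accessions=accs, region_counts=regions)


def expressed_in(
    expr: ExpressionMatrix,
    transcript_id: str,
    accession: str,
    min_fpkm: float = 0.1,
) -> bool:
    """True iff mean FPKM reaches ``min_fpkm`` in >=1 condition (inclusive)."""
    if transcript_id not in expr.values.index:
        raise KeyError(f"unknown transcript {transcript_id!r}")
    row = expr.values.loc[transcript_id]
    for condition in ("control", "drought"):
        cols = expr.samples_for(accession, condition)
        if cols and row[cols].mean() >= min_fpkm:
            return True
    return False


@dataclass(frozen=True)
class GoLink:
    pair: NATPair
    go_id: str
    accessions: frozenset


def go_link(
    pairs: Sequence[NATPair],
    gene2go: Mapping[str, Iterable[str]],
    stress_terms: Iterable[str] = STRESS_TERMS,
    responsive_accessions: Optional[Mapping[tuple[str, str], Iterable[str]]] = None,
) -> list[GoLink]:
    """Link coding-noncoding pairs to stress GO terms via the sense gene.

    Each pair is emitted once per stress term annotated on its sense gene,
    together with the accession set in which the pair is responsive (looked
    up by (sense_id, antisense_id); unannotated genes never match).
    """
    stress = set(stress_terms)
    responsive = responsive_accessions or {}
    out = []
    for p in pairs:
        if p.coding_class != "coding_noncoding":
            continue
        terms = set(gene2go.get(p.sense.gene_id, ())) & stress
        accs = frozenset(responsive.get(p.key, ()))
        for term in sorted(terms):
            out.append(GoLink(pair=p, go_id=term, accessions=accs))
    out.sort(key=lambda g: (g.pair.chrom, g.pair.overlap_start, g.pair.sense_id, g.go_id))
    return out


def enrich_hypergeom(
    study: Iterable[str],
    population: Iterable[str],
    gene2go: Mapping[str, Iterable[str]],
) -> pd.DataFrame:
    """Flat hypergeometric GO-term enrichment of a study set.

    For each term with >=1 study gene: k study genes with the term out of
    n = |study|, K population genes with the term out of N = |population|;
    p = P(X >= k) for X ~ Hypergeometric(N, K, n), q by BH across tested
    terms.  Terms are matched exactly as annotated (no GO-graph
    propagation).
    """
    study_set = set(study)
    pop_set = set(population)
    outside = study_set - pop_set
    if outside:
        raise ValueError(
            f"study gene(s) outside the population: {sorted(outside)[:5]}"
        )
    n, N = len(study_set), len(pop_set)
    term_k: dict[str, int] = {}
    term_K: dict[str, int] = {}
    for gene in pop_set:
        for term in set(gene2go.get(gene, ())):
            term_K[term] = term_K.get(term, 0) + 1
            if gene in study_set:
                term_k[term] = term_k.get(term, 0) + 1
    terms = sorted(term_k)
    if not terms:
        return pd.DataFrame(columns=["go_id", "k", "K", "n", "N", "p", "q"])
    p = np.array(
        [stats.hypergeom.sf(term_k[t] - 1, N, term_K[t], n) for t in terms]
    )
    p = np.clip(p, 0.0, 1.0)
    q = multipletests(p, method="fdr_bh")[1]
    out = pd.DataFrame(
        {
            "go_id": terms,
            "k": [term_k[t] for t in terms],
            "K": [term_K[t] for t in terms],
            "n": n,
            "N": N,
            "p": p,
            "q": q,
        }
    )
    return out.sort_values(["p", "go_id"], kind="stable").reset_index(drop=True)
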