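import itertools
import math
import subprocess

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from natpairs import (
    ExpressionMatrix,
    call_de,
    classify_pair_response,
    enrich_hypergeom,
    expressed_in,
    go_link,
    scan_pairs,
    venn_partition,
)
from natpairs.response import _de_pvalues
from natpairs.simulate import table1_fixture, table1_transcripts

from conftest import make_tx, venn_sets_from_regions

ACCS = ("Nip", "BJ89", "BJ278")


def expr_matrix(rows, accessions=("Nip",), n_reps=3):
    """rows: transcript_id -> {(accession, condition): [replicate FPKMs]}"""
    samples, meta = [], []
    for acc in accessions:
        for cond in ("control", "drought"):
            for rep in range(1, n_reps + 1):
                samples.append(f"{acc}_{cond}_{rep}")
                meta.append(
                    {"sample_id": samples[-1], "accession": acc,
                     "condition": cond, "replicate": rep}
                )
    data = {}
    for tid, cells in rows.items():
        vals = []
        for acc in accessions:
            for cond in ("control", "drought"):
                vals.extend(cells[(acc, cond)])
        data[tid] = vals
    values = pd.DataFrame.from_dict(data, orient="index", columns=samples)
    values.index.name = "transcript_id"
    return ExpressionMatrix(values=values, meta=pd.DataFrame(meta).set_index("sample_id"))


class TestCallDe:
    def test_flat_transcript_not_called(self):
        expr = expr_matrix(
            {"T1": {("Nip", "control"): [5, 5, 5], ("Nip", "drought"): [5, 5, 5]}}
        )
        res = call_de(expr, "Nip")
        assert res.loc["T1", "log2fc"] == 0
        assert res.loc["T1", "call"] == "none"
        assert res.loc["T1", "direction"] == "none"

    def test_pseudocounted_fold_change_hand_arithmetic(self):
        expr = expr_matrix(
            {"T1": {("Nip", "control"): [1, 1, 1], ("Nip", "drought"): [8, 8, 8]}}
        )
        res = call_de(expr, "Nip")
        # (8 + 1) / (1 + 1) = 4.5
        assert res.loc["T1", "log2fc"] == pytest.approx(math.log2(4.5))
        if res.loc["T1", "call"] != "none":
            assert res.loc["T1", "direction"] == "up"

    def test_unknown_accession_errors(self):
        expr = expr_matrix(
            {"T1": {("Nip", "control"): [1, 1, 1], ("Nip", "drought"): [2, 2, 2]}}
        )
        with pytest.raises(KeyError, match="BJ89"):
            call_de(expr, "BJ89")

    def test_single_replicate_errors(self):
        expr = expr_matrix(
            {"T1": {("Nip", "control"): [1], ("Nip", "drought"): [2]}},
            n_reps=1,
        )
        with pytest.raises(ValueError, match="replicates"):
            call_de(expr, "Nip")

    def test_hdeg_set_subset_of_deg_set(self):
        rng = np.random.default_rng(9)
        rows = {}
        for i in range(300):
            base = float(rng.uniform(1, 50))
            shift = float(rng.choice([1.0, 2.5, 5.0, 9.0]))
            rows[f"T{i}"] = {
                ("Nip", "control"): list(base * rng.lognormal(0, 0.2, 3)),
                ("Nip", "drought"): list(base * shift * rng.lognormal(0, 0.2, 3)),
            }
        expr = expr_matrix(rows)
        res = call_de(expr, "Nip")
        hdeg = set(res[res["call"] == "HDEG"].index)
        deg = set(res[res["call"].isin(["DEG", "HDEG"])].index)
        assert hdeg <= deg
        # raising the fold-change bar to 4 reproduces exactly the HDEG set
        res4 = call_de(expr, "Nip", fc_threshold=4.0)
        assert set(res4[res4["call"] != "none"].index) == hdeg

    def test_bh_q_dominates_p_and_is_monotone(self):
        rng = np.random.default_rng(10)
        rows = {
            f"T{i}": {
                ("Nip", "control"): list(rng.lognormal(2, 0.3, 3)),
                ("Nip", "drought"): list(rng.lognormal(2 + rng.normal(0, 1), 0.3, 3)),
            }
            for i in range(200)
        }
        res = call_de(expr_matrix(rows), "Nip")
        assert (res["q"] >= res["p"] - 1e-12).all()
        srt = res.sort_values("p")
        assert (np.diff(srt["q"].to_numpy()) >= -1e-12).all()

    def test_moderated_pvalues_match_limma_oracle(self, tmp_path):
        """Cross-check the empirical-Bayes moderated t against R limma."""
        rng = np.random.default_rng(42)
        n, reps = 60, 3
        sds = rng.uniform(0.1, 1.2, n)  # heteroskedastic rows
        lc = rng.normal(5, 1, n)[:, None] + rng.normal(0, sds[:, None], (n, reps))
        ld = lc.mean(axis=1, keepdims=True) + rng.normal(0, sds[:, None], (n, reps))
        ld[: n // 4] += 2.0
        ours = _de_pvalues(ld, lc, "moderated")
        mat = pd.DataFrame(
            np.hstack([lc, ld]),
            index=[f"T{i}" for i in range(n)],
            columns=[f"c{i}" for i in range(reps)] + [f"d{i}" for i in range(reps)],
        )
        mat_path = tmp_path / "mat.tsv"
        out_path = tmp_path / "p.tsv"
        mat.to_csv(mat_path, sep="\t")
        script = tmp_path / "limma.R"
        script.write_text(
            "suppressMessages(library(limma))\n"
            f"x <- as.matrix(read.table('{mat_path}', sep='\\t', header=TRUE, "
            "row.names=1))\n"
            "design <- cbind(Intercept=1, drought=c(0,0,0,1,1,1))\n"
            "fit <- eBayes(lmFit(x, design), trend=FALSE)\n"
            "write.table(data.frame(p=fit$p.value[,'drought']), "
            f"'{out_path}', sep='\\t', quote=FALSE)\n"
        )
        subprocess.run(["Rscript", str(script)], check=True, capture_output=True)
        limma_p = pd.read_csv(out_path, sep="\t", index_col=0)["p"].to_numpy()
        assert np.allclose(ours, limma_p, rtol=1e-4, atol=1e-12)


class TestPairResponse:
    def _setup(self, sense_lfc, anti_lfc, sense_call="DEG", anti_call="DEG"):
        sense = make_tx("S", start=100, end=900, strand="+")
        anti = make_tx("A", start=400, end=1300, strand="-", coding="noncoding")
        (pair,) = scan_pairs([sense, anti])
        de = {
            "Nip": pd.DataFrame(
                {
                    "log2fc": [sense_lfc, anti_lfc],
                    "call": [sense_call, anti_call],
                    "direction": [
                        ("up" if sense_lfc > 0 else "down") if sense_call != "none" else "none",
                        ("up" if anti_lfc > 0 else "down") if anti_call != "none" else "none",
                    ],
                },
                index=["S", "A"],
            )
        }
        return pair, de

    def test_both_up_is_concordant_up(self):
        pair, de = self._setup(2.0, 3.0)
        assert classify_pair_response(pair, de, "Nip").status == "concordant_up"

    def test_both_down_is_concordant_down(self):
        pair, de = self._setup(-2.0, -3.0)
        assert classify_pair_response(pair, de, "Nip").status == "concordant_down"

    def test_opposite_directions_is_discordant(self):
        pair, de = self._setup(2.0, -3.0)
        assert classify_pair_response(pair, de, "Nip").status == "discordant"

    def test_one_member_below_threshold_not_responsive(self):
        pair, de = self._setup(2.0, 0.5, anti_call="none")
        assert classify_pair_response(pair, de, "Nip").status == "not_responsive"

    def test_missing_result_names_transcript_and_accession(self):
        pair, de = self._setup(2.0, 2.0)
        de["Nip"] = de["Nip"].drop(index="A")
        with pytest.raises(KeyError, match="A.*Nip"):
            classify_pair_response(pair, de, "Nip")

    def test_both_deg_always_exactly_one_response_class(self):
        for s_dir, a_dir in itertools.product(["up", "down"], repeat=2):
            lfc = {"up": 2.0, "down": -2.0}
            pair, de = self._setup(lfc[s_dir], lfc[a_dir])
            status = classify_pair_response(pair, de, "Nip").status
            assert status in ("concordant_up", "concordant_down", "discordant")


class TestVennPartition:
    def test_single_shared_item(self):
        part = venn_partition({a: {1} for a in ACCS}, ACCS)
        assert part.region_counts[ACCS] == 1
        assert part.union == 1

    def test_printed_de_lncrna_regions(self):
        regions = {
            ("Nip",): 61, ("BJ89",): 139, ("BJ278",): 92,
            ("Nip", "BJ89"): 20, ("Nip", "BJ278"): 14, ("BJ89", "BJ278"): 45,
            ACCS: 23,
        }
        part = venn_partition(venn_sets_from_regions(regions, ACCS), ACCS)
        assert part.union == 394
        assert part.marginal("Nip") == 118
        assert part.marginal("BJ89") == 227
        assert part.marginal("BJ278") == 174

    def test_printed_discordant_pair_regions(self):
        regions = {
            ("Nip",): 6, ("BJ89",): 6, ("BJ278",): 8,
            ("Nip", "BJ89"): 0, ("Nip", "BJ278"): 1, ("BJ89", "BJ278"): 2,
            ACCS: 1,
        }
        part = venn_partition(venn_sets_from_regions(regions, ACCS), ACCS)
        assert part.union == 24

    def test_unknown_accession_errors(self):
        with pytest.raises(ValueError, match="unknown accession"):
            venn_partition({"Nip": {1}, "XYZ": {2}}, ACCS)

    def test_needs_exactly_three(self):
        with pytest.raises(ValueError, match="exactly 3"):
            venn_partition({"A": {1}}, ("A", "B"))

    @settings(derandomize=True, max_examples=100)
    @given(
        a=st.sets(st.integers(0, 40)),
        b=st.sets(st.integers(0, 40)),
        c=st.sets(st.integers(0, 40)),
    )
    def test_regions_conserve_union_and_marginals(self, a, b, c):
        part = venn_partition({"A": a, "B": b, "C": c}, ("A", "B", "C"))
        assert part.union == len(a | b | c)
        assert part.marginal("A") == len(a)
        assert part.marginal("B") == len(b)
        assert part.marginal("C") == len(c)


class TestExpressedIn:
    def _expr(self, control, drought):
        return expr_matrix(
            {"T1": {("Nip", "control"): control, ("Nip", "drought"): drought}}
        )

    def test_all_zero_not_expressed(self):
        assert not expressed_in(self._expr([0, 0, 0], [0, 0, 0]), "T1", "Nip")

    def test_either_condition_suffices(self):
        assert expressed_in(self._expr([0, 0, 0], [0.2, 0.2, 0.2]), "T1", "Nip")

    def test_boundary_inclusive(self):
        assert expressed_in(self._expr([0, 0, 0], [0.1, 0.1, 0.1]), "T1", "Nip")

    def test_unknown_transcript_errors(self):
        with pytest.raises(KeyError, match="T9"):
            expressed_in(self._expr([1, 1, 1], [1, 1, 1]), "T9", "Nip")


class TestGoLink:
    def _fixture_links(self, stress_terms=None):
        pairs_df, gene2go_df, membership = table1_fixture()
        pairs = scan_pairs(table1_transcripts())
        gene2go = {
            g: set(grp["go_id"]) for g, grp in gene2go_df.groupby("gene_id")
        }
        responsive = {
            (r.sense_id, r.antisense_id): set(
                membership[
                    (membership.sense_id == r.sense_id)
                    & (membership.antisense_id == r.antisense_id)
                ]["accession"]
            )
            for r in membership.itertuples(index=False)
        }
        kwargs = {} if stress_terms is None else {"stress_terms": stress_terms}
        return go_link(pairs, gene2go, responsive_accessions=responsive, **kwargs)

    def test_nine_pairs_unique_to_wild_rice(self):
        links = self._fixture_links()
        nivara_only = {
            l.pair.key for l in links if "Nip" not in l.accessions
        }
        assert len(nivara_only) == 9

    def test_one_pair_in_all_accessions(self):
        links = self._fixture_links()
        all_three = [
            l for l in links if l.accessions == frozenset(ACCS)
        ]
        assert len(all_three) == 1
        assert all_three[0].pair.chrom == "chr08"

    def test_empty_stress_terms_yield_nothing(self):
        assert self._fixture_links(stress_terms=set()) == []


class TestEnrichHypergeom:
    def test_study_equals_population_gives_p_one(self):
        gene2go = {f"g{i}": {"GO:1"} if i < 4 else {"GO:2"} for i in range(10)}
        pop = set(gene2go)
        res = enrich_hypergeom(pop, pop, gene2go)
        assert np.allclose(res["p"], 1.0)

    def test_all_annotated_drawn_matches_closed_form(self):
        # N=20, K=5, n=5, k=5 -> p = 1 / C(20,5)
        genes = [f"g{i}" for i in range(20)]
        gene2go = {g: {"GO:X"} for g in genes[:5]}
        res = enrich_hypergeom(set(genes[:5]), set(genes), gene2go)
        assert res.loc[0, "p"] == pytest.approx(1 / math.comb(20, 5), rel=1e-12)

    def test_matches_exhaustive_enumeration(self):
        rng = np.random.default_rng(5)
        genes = [f"g{i}" for i in range(12)]
        gene2go = {
            g: {t for t in ("GO:A", "GO:B") if rng.random() < 0.4} for g in genes
        }
        study = set(rng.choice(genes, size=5, replace=False))
        res = enrich_hypergeom(study, set(genes), gene2go).set_index("go_id")
        n = len(study)
        for term in res.index:
            K_genes = {g for g in genes if term in gene2go[g]}
            k = len(study & K_genes)
            total = hits = 0
            for draw in itertools.combinations(genes, n):
                total += 1
                hits += len(set(draw) & K_genes) >= k
            assert res.loc[term, "p"] == pytest.approx(hits / total, rel=1e-9)

    def test_unannotated_terms_absent(self):
        gene2go = {"g1": {"GO:A"}, "g2": {"GO:B"}}
        res = enrich_hypergeom({"g1"}, {"g1", "g2"}, gene2go)
        assert set(res["go_id"]) == {"GO:A"}

    def test_study_outside_population_errors(self):
        with pytest.raises(ValueError, match="outside"):
            enrich_hypergeom({"gX"}, {"g1"}, {})
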