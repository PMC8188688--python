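# Methods

## Scope and model

`natpairs` analyses cis-natural antisense transcription in a stranded,
annotated transcriptome with replicated two-condition FPKM expression over
several accessions. It does not touch reads: mapping, assembly and FPKM
estimation are upstream. Its objects are transcript models (1-based
inclusive genomic spans with exon chains and a coding-capacity flag),
opposite-strand transcript pairs, per-accession differential-expression
calls, and set partitions of findings across accessions.

All internal coordinates are 1-based inclusive (GTF native); BED output
converts to 0-based half-open at the boundary and nowhere else. This keeps
printed coordinate tables usable verbatim in tests and examples.

## Coding capacity

Dedicated coding-potential tools operate on sequence databases and are out
of scope; the package resolves coding capacity by precedence:

1. an explicit override table (transcript_id → coding/noncoding) — the
   intended path for real analyses, where flags come from upstream tools;
2. a longest-ORF heuristic on a supplied transcript sequence: coding iff
   some forward-frame ATG→stop ORF reaches `min_orf_codons` (default 100)
   codons, counted from the ATG to the last codon before the stop; an ORF
   that never reaches a stop does not count;
3. a flag already present on the transcript.

An unresolved flag is an error before classification or pair scanning, so
coding-class labels are never silently guessed.

## lncRNA cascade

Categories are assigned in a fixed order so every transcript lands in
exactly one bin: coding → `mRNA`; noncoding with spliced length < 200 nt →
`excluded_short`; on the small-RNA exclusion list (e.g. Rfam hits, supplied
as ids) → `excluded_smallRNA`; otherwise `lncNAT` if the genomic span
overlaps any coding transcript's span by ≥ 1 bp on the opposite strand of
the same chromosome, else `lincRNA`. The 200 nt floor is inclusive
(≥ 200), the conventional lncRNA definition, and is applied to spliced
(exon-sum) length. The lncNAT/lincRNA split deliberately uses the ≥ 1 bp
"overlapped" notion; the stricter ≥ 25 nt threshold belongs to pair
calling, which is a separate question.

## Pair scan and orientation

Pairs are found per chromosome with an interval tree over minus-strand
spans queried by plus-strand spans, so cost is near-linear in transcripts
plus overlaps; an all-pairs double loop is retained in the tests as an
independent oracle. The overlap threshold (`min_overlap`, default 25 nt,
inclusive) applies to genomic spans by default; `overlap_mode="exon"`
applies it to the exon-union intersection instead, for annotations where
span overlap overstates the antisense contact. Pair identity is at the
transcript (isoform) level: two isoforms against the same antisense
partner are two pairs.

Orientation is decided on spans: containment in either direction
(boundaries included, identical spans too) is **enclosed**; otherwise with
P = [p1, p2] the plus member and M = [m1, m2] the minus member,
m1 < p1 ≤ m2 < p2 (overlap covering both 5′ ends) is **divergent** and
p1 < m1 ≤ p2 < m2 (both 3′ ends) is **convergent**. These three cases are
exhaustive for any overlapping opposite-strand pair. A useful symmetry,
checked by property test: reflecting all coordinates (x → L − x) without
touching strands swaps divergent ↔ convergent and preserves enclosed;
reflecting *and* flipping strands maps every 5′ end back to a 5′ end and
therefore preserves all three classes.

For coding–noncoding pairs the sense member is the coding transcript and
the antisense member the lncRNA; for same-class pairs, sense defaults to
the plus-strand member (a reporting convention only).

## Differential expression and pair response

Per accession, fold change is the pseudocounted ratio
`(mean FPKM_drought + ε) / (mean FPKM_control + ε)` with ε = 1 FPKM, which
keeps condition-specific transcripts finite and well-ordered; the DEG
threshold (`FC ≥ 2`, either direction) and HDEG threshold (`FC ≥ 4`) apply
to this ratio, both at BH-FDR q ≤ 0.01 computed across all transcripts
tested in that accession (mirroring one differential-expression run per
accession contrast). HDEG ⊆ DEG by construction.

The replicate-level test statistic operates on log2(FPKM + ε). The default
(`method="moderated"`) is a moderated t-statistic: per-transcript pooled
variances (df = n1 + n2 − 2) are shrunk toward a common prior fitted by
matching the first two moments of log s² to a scaled-F model — the
empirical-Bayes squeeze used by limma — and the t-statistic uses the
posterior variance with df + d0 degrees of freedom (Gaussian when the
variances are consistent with a single common value, d0 → ∞). With 2–3
replicates per condition, raw per-transcript variances are so noisy that a
plain Welch test loses a material fraction of genuine 8-fold effects at
q ≤ 0.01 — and a *pair* is only called when **both** members pass, which
squares the loss. The implementation is cross-checked against R limma
(`lmFit` + `eBayes`) on a heteroskedastic matrix in the test suite. Plain
Welch remains available as `method="welch"`; both sit behind the same
`call_de` interface. Zero-variance corner cases resolve to p = 1 when the
group means agree and p = 0 when they differ.

A pair's response status in an accession is determined only by its two
members' calls: both DEG and same direction → `concordant_up` /
`concordant_down`; both DEG, opposite directions → `discordant`; anything
less → `not_responsive`. Any (DEG, DEG) pair falls in exactly one of the
three responsive classes.

## Accession partitioning, GO linking, enrichment

`venn_partition` computes the exact 7-region decomposition of a membership
map over an ordered accession triple; region counts always sum to the
union and marginals reconstruct per-accession totals. "Expressed in an
accession" means mean FPKM ≥ `min_fpkm` (default 0.1, inclusive) in at
least one condition — the cutoff must be explicit to partition expressed
pairs at all, and is configurable.

`go_link` emits each responsive coding–noncoding pair once per stress GO
term annotated on its sense gene, with the accession set in which the pair
is responsive. `enrich_hypergeom` is a flat upper-tail hypergeometric test
(P(X ≥ k) with k of n study genes vs K of N population genes annotated),
BH-adjusted across tested terms; terms are matched exactly as annotated,
with no GO-graph propagation.

## Bench formulas

Relative water loss is (FW − CW)/FW for a detached leaf of fresh weight FW
and current weight CW; negative values (CW > FW) are returned with a
warning rather than clipped, since they flag weighing noise that should
stay visible. Relative qPCR expression is 2^(−ΔΔCt) with
ΔΔCt = (Ct_target − Ct_ref)_treated − (Ct_target − Ct_ref)_control;
swapping treated and control inverts the fold change exactly.

## Synthetic data

The generator emulates the study design the pipeline targets: 3 accessions
× control/drought × 3 replicates, ~1000 transcripts by default (600 coding,
400 noncoding), planted 8-fold effects (|log2fc| = 3) and log-normal
replicate noise (Normal sd 0.25 on the log2-FPKM scale, exponentiated).
Baseline log2 FPKM is uniform on [2, 7].

Placement: each locus (a planted pair or a standalone transcript) gets a
disjoint genomic slot (500 bp gaps, loci cycled over 4 chromosomes of 2 Mb
by default), so the only opposite-strand overlaps in the output are the
planted ones — recovery comparisons against ground truth are exact by
construction, and placement is deterministic for a seed (byte-identical
outputs). Infeasible packing raises with a remedy (larger chromosomes).
Pair coordinates are built by solving the orientation inequalities
directly, so planted labels are correct by construction; overlap lengths
are drawn from `pair_overlap_range` (default [25, 2000]), and a noncoding
member is never given a span below the 200 nt lncRNA floor (for short
enclosed overlaps the lncRNA takes the outer span). Each noncoding
transcript draws an orientation from `orientation_mix` ("none" →
standalone lincRNA, otherwise paired with a coding partner); leftover
coding transcripts pair among themselves, so coding–coding pairs exist
even with no lncRNAs. Noncoding–noncoding pairs are not generated — the
drought-response analysis the generator exercises centres on
coding–noncoding pairs, and the scan itself is covered by the random-
annotation oracle tests.

Each planted pair draws a response class (`response_mix`, default
0.3/0.3/0.3/0.1 over concordant-up/concordant-down/discordant/null) and is
designated responsive independently per accession with probability 0.7 (at
least one accession for non-null classes); designated accessions receive
the class's (sense, antisense) log2 effects under drought, others none.

What the generator does **not** emulate: read-count sampling noise (FPKM
is log-normal, not negative-binomial), mean–variance trends, isoform
sharing between pairs, trans-NATs, unstranded contamination, or
accession-specific annotations. Passing recovery tests therefore
demonstrates the correctness of the classification, scanning, thresholding
and partitioning logic under the declared noise model — not the end-to-end
power of the upstream assembly/quantification stack on real reads.

## Fixture of printed pairs

`table1_fixture()` returns the ten stress-linked coding–noncoding pair
coordinates (with GO terms and accession membership) as byte-stable
tables, and `table1_transcripts()` the corresponding toy annotation with
the coding sense member on + and the lncRNA on −. The printed table has no
strand columns, so sense strands are a fixture convention; containment
status and overlap arithmetic are strand-free and match the printed
coordinates exactly.

## Numerical and problem-size choices

Tests and the acceptance script run simulations at ~200–1000 transcripts
and 20 seeds — large enough that recovery and realized-FDR estimates are
stable (≈800 planted pair-responses and ≈33,000 DEG calls pooled over
seeds), small enough to iterate quickly. The brute-force scanner oracle
runs on 200 random annotations of up to 500 transcripts. Determinism:
every stochastic component takes a single integer seed through
`numpy.random.default_rng`; hypothesis property tests are derandomized.

## Known limitations

- Span-mode overlap can overstate antisense contact for multi-exon
  transcripts whose exons interleave; exon mode exists but Table-style
  printed coordinates validate span mode only.
- The moderated test assumes roughly additive log-scale noise; with
  heavy-tailed FPKM error at very low expression the pseudocount dominates
  and calls become conservative.
- GO enrichment is flat (no ontology propagation) and the stress-term list
  is a user input, defaulting to the four terms of the shipped fixture.
- The Venn layer is fixed at exactly three sets, matching the
  three-accession design; other designs need a different partitioning.
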