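# natpairs

Strand-aware detection and drought-response analysis of **natural antisense
transcript (NAT) pairs** in stranded transcriptomes, built for the rice
drought-stress setting (cultivated Nipponbare vs the wild-rice *Oryza
nivara* accessions BJ89 and BJ278) but applicable to any multi-accession,
two-condition, replicated FPKM study.

A cis-NAT pair is two transcripts on opposite strands of the same locus
whose genomic spans overlap. Long noncoding NATs (lncNATs) can regulate
their sense partners, so the pipeline answers, end to end:

1. **Which transcripts are lncRNAs, and of what kind?** Coding transcripts
   are mRNA; noncoding transcripts ≥ 200 nt (spliced) that overlap a coding
   gene on the opposite strand are lncNATs, the rest are lincRNAs; shorter
   or small-RNA-listed transcripts are excluded.
2. **Which transcripts form NAT pairs?** All opposite-strand pairs with
   span overlap ≥ 25 nt, typed as *enclosed* (one span contains the other),
   *divergent* (head-to-head, 5′-end overlap) or *convergent* (tail-to-tail,
   3′-end overlap), and as coding–coding / coding–noncoding /
   noncoding–noncoding.
3. **Which pairs respond to drought?** Per accession, a transcript is a DEG
   when its pseudocounted fold change `FC = (mean FPKM_drought + 1) /
   (mean FPKM_control + 1)` satisfies `FC ≥ 2` (either direction) at
   BH-FDR `q ≤ 0.01` (HDEG at `FC ≥ 4`); p-values come from a moderated
   t-statistic on log₂(FPKM + 1) with empirical-Bayes variance shrinkage
   across transcripts. A pair is *concordant* (up/down) when both members
   are DEGs moving together and *discordant* when they oppose.
4. **How do findings partition across accessions?** Exact 7-region Venn
   decompositions over the three accessions, plus GO linking of responsive
   coding–noncoding pairs to stress terms and a flat hypergeometric
   enrichment.

The package also includes the two bench formulas that accompany such
studies — relative water loss `(FW − CW)/FW` and qPCR fold change
`2^(−ΔΔCt)` — and a synthetic-data generator that plants pairs with known
orientation and per-accession response status so every stage is testable
against ground truth.

## Worked example

The ten stress-linked coding–noncoding pairs ship as a machine-readable
fixture. Scanning their coordinates:

```python
from natpairs import scan_pairs, pairs_to_frame, table1_transcripts

pairs = scan_pairs(table1_transcripts(), min_overlap=25)
print(pairs_to_frame(pairs).to_string(index=False))
```

```
chrom        sense_id  sense_start  sense_end    antisense_id  antisense_start  antisense_end  overlap_len orientation     coding_class
chr01    MSTRG.1295.1      8546015    8546972 Os01t0256500-02          8546065        8546869          805    enclosed coding_noncoding
chr03 Os03t0161900-02      3342254    3344542   MSTRG.10570.1          3342143        3344510         2257   divergent coding_noncoding
chr03 Os03t0161900-01      3342277    3344547   MSTRG.10570.1          3342143        3344510         2234   divergent coding_noncoding
chr03   MSTRG.12385.1     16407687   16410061 Os03t0402800-02         16407695       16408985         1291    enclosed coding_noncoding
chr03   MSTRG.12385.1     16407687   16410061 Os03t0402800-01         16407699       16410007         2309    enclosed coding_noncoding
chr04 Os04t0497700-01     24889983   24891470   MSTRG.16704.1         24889504       24891481         1488    enclosed coding_noncoding
chr07 Os07t0615200-01     25348060   25350242   MSTRG.27311.1         25348061       25350279         2182  convergent coding_noncoding
chr08 Os08t0504700-01     24953937   24954919   MSTRG.30183.1         24953534       24955156          983    enclosed coding_noncoding
chr09   MSTRG.30767.1       656756     658373 Os09t0106700-01           656788         658373         1586    enclosed coding_noncoding
chr09   MSTRG.31075.1      5538425    5540535 Os09t0273600-00          5538561        5539063          503    enclosed coding_noncoding
```

All ten coordinate pairs pass the ≥ 25 nt criterion; the chr01 pair's
overlap is 805 bp and it is enclosed (the lncRNA sits inside the sense
span). A transcript can appear in several pairs (two Os03t0161900 isoforms
against the same lncRNA; one MSTRG.12385.1 against two antisense isoforms).

The model/results interface runs the whole pipeline on a synthetic study
(3 accessions × control/drought × 3 replicates):

```python
from natpairs import NATPairAnalysis, simulate, SimSpec

sim = simulate(SimSpec(seed=42, n_coding=120, n_lnc=80))
sim.to_dir("sim/")
model = NATPairAnalysis.from_files(
    "sim/sim.gtf", expression_path="sim/fpkm.tsv",
    meta_path="sim/meta.tsv", coding_path="sim/coding.tsv",
)
print(model.fit().summary())
```

```
NAT-pair analysis summary
=========================
Transcript categories:
  mRNA                  120
  lincRNA                12
  lncNAT                 68
NAT pairs (total): 90
  by orientation:
    enclosed                 37 (41.11%)
    convergent               27 (30.00%)
    divergent                26 (28.89%)
  by coding_class:
    coding_noncoding         68 (75.56%)
    coding_coding            22 (24.44%)
Drought-responsive pairs per accession:
  Nip         57  {'concordant_down': 20, 'discordant': 20, 'concordant_up': 17}
  BJ89        54  {'discordant': 20, 'concordant_up': 19, 'concordant_down': 15}
  BJ278       59  {'concordant_down': 24, 'concordant_up': 20, 'discordant': 15}
Responsive-pair union across accessions: 77
```

Here 68 of the 80 planted lncRNAs were planted as antisense partners of
coding genes (lncNAT) and 12 as intergenic (lincRNA); the scanner recovers
exactly the planted pairs, and the per-accession response counts reflect
the planted concordant/discordant effects (8-fold, log-normal replicate
noise).

The same steps are available from the shell:

```bash
natpairs fixtures table1 --outdir fx/
natpairs scan --gtf fx/annotation.gtf --coding fx/coding.tsv --out pairs.tsv
natpairs simulate --seed 42 --outdir sim/
natpairs respond --gtf sim/sim.gtf --expr sim/fpkm.tsv --meta sim/meta.tsv \
    --coding sim/coding.tsv --out response.tsv
```

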