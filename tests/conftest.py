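import numpy as np
import pytest

from natpairs import Transcript


def make_tx(
    tid,
    chrom="chr1",
    start=100,
    end=500,
    strand="+",
    coding="coding",
    exons=None,
    gene=None,
):
    return Transcript(
        transcript_id=tid,
        gene_id=gene or f"g_{tid}",
        chrom=chrom,
        start=start,
        end=end,
        strand=strand,
        exons=tuple(exons) if exons else ((start, end),),
        coding=coding,
    )


@pytest.fixture
def tx():
    """Factory for toy transcripts."""
    return make_tx


def random_transcripts(rng, n, n_chroms=2, genome_span=50_000):
    """Random stranded single-exon transcripts for oracle comparisons."""
    ts = []
    for i in range(n):
        start = int(rng.integers(1, genome_span))
        length = int(rng.integers(50, 5000))
        ts.append(
            make_tx(
                f"T{i}",
                chrom=f"chr{int(rng.integers(1, n_chroms + 1))}",
                start=start,
                end=start + length - 1,
                strand="+" if rng.random() < 0.5 else "-",
                coding="coding" if rng.random() < 0.5 else "noncoding",
            )
        )
    return ts


def brute_force_pairs(transcripts, min_overlap=25):
    """Independent all-pairs oracle for the NAT-pair scan.

    Double loop over transcript pairs; orientation decided by which
    transcript ends fall inside the shared interval (end-membership), not
    by the inequality chain the implementation uses.
    """
    out = set()
    n = len(transcripts)
    for i in range(n):
        for j in range(i + 1, n):
            a, b = transcripts[i], transcripts[j]
            if a.chrom != b.chrom or a.strand == b.strand:
                continue
            lo, hi = max(a.start, b.start), min(a.end, b.end)
            ov = hi - lo + 1
            if ov < min_overlap:
                continue
            p = a if a.strand == "+" else b
            m = b if p is a else a
            if (p.start <= m.start and m.end <= p.end) or (
                m.start <= p.start and p.end <= m.end
            ):
                ori = "enclosed"
            elif lo <= p.start <= hi and lo <= m.end <= hi:
                ori = "divergent"  # overlap covers both 5' ends
            elif lo <= p.end <= hi and lo <= m.start <= hi:
                ori = "convergent"  # overlap covers both 3' ends
            else:  # pragma: no cover
                raise AssertionError("oracle: overlap without orientation")
            n_coding = (a.coding == "coding") + (b.coding == "coding")
            cclass = ("noncoding_noncoding", "coding_noncoding", "coding_coding")[
                n_coding
            ]
            out.add(
                (a.chrom, p.transcript_id, m.transcript_id, ov, lo, hi, ori, cclass)
            )
    return out


def pairs_as_tuples(pairs):
    return {
        (
            p.chrom,
            p.plus.transcript_id,
            p.minus.transcript_id,
            p.overlap_len,
            p.overlap_start,
            p.overlap_end,
            p.orientation,
            p.coding_class,
        )
        for p in pairs
    }


def venn_sets_from_regions(region_counts, accessions):
    """Membership sets realizing given 7-region Venn counts."""
    members = {a: set() for a in accessions}
    item = 0
    for combo, count in region_counts.items():
        for _ in range(count):
            item += 1
            for a in combo:
                members[a].add(item)
    return members
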