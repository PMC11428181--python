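"""Peak categories, TSS association and lincS calling."""
import numpy as np
import pytest

from stemlinc import (
    AnnotationSet,
    GeneModel,
    Peak,
    annotate_peaks,
    associate_peak,
    call_lincS,
    categorize_peak,
    distribution,
    make_genome,
    tss_distances,
)
from conftest import oracle_associations


@pytest.fixture
def toy_annotation():
    """One 3-exon plus-strand coding gene at 10000-16000 on a 100 kb chrom."""
    gene = GeneModel(
        gene_id="gA", chrom="chr1", start=10_000, end=16_000, strand="+",
        biotype="protein_coding",
        exons=((10_000, 10_500), (12_000, 12_400), (15_000, 16_000)),
    )
    return AnnotationSet(genes=[gene], chrom_sizes={"chr1": 100_000})


def _peak_at(summit, chrom="chr1"):
    return Peak(chrom=chrom, start=summit - 100, end=summit + 100, summit=summit)


@pytest.mark.parametrize(
    "summit,expected",
    [
        (9_700, "promoter"),        # 300 bp upstream of the TSS
        (10_990, "promoter"),       # inside exon 1 but within the TSS window
        (11_500, "first_intron"),   # intron 1, outside the promoter window
        (13_000, "other_intron"),
        (12_200, "exon_coding"),
        (15_500, "exon_coding"),
        (24_000, "distal_intergenic"),  # 8 kb past the gene body
    ],
)
def test_categorize_by_summit(toy_annotation, summit, expected):
    assert categorize_peak(_peak_at(summit), toy_annotation) == expected


def test_categorize_unknown_chromosome(toy_annotation):
    with pytest.raises(ValueError, match="chromosome"):
        categorize_peak(_peak_at(5_000, chrom="chrX"), toy_annotation)


def test_first_intron_is_strand_aware():
    """On a minus-strand gene the first intron is the right-most one."""
    gene = GeneModel(
        gene_id="gB", chrom="chr1", start=10_000, end=16_000, strand="-",
        biotype="lincRNA",
        exons=((10_000, 10_500), (12_000, 12_400), (15_000, 16_000)),
    )
    ann = AnnotationSet(genes=[gene], chrom_sizes={"chr1": 100_000})
    assert categorize_peak(_peak_at(13_000), ann) == "first_intron"
    assert categorize_peak(_peak_at(11_500), ann) == "other_intron"


def test_distribution_sums_to_one(toy_annotation):
    peaks = [_peak_at(s) for s in (9_700, 9_800, 11_500, 24_000)]
    fractions = distribution(annotate_peaks(peaks, toy_annotation))
    assert sum(fractions.values()) == pytest.approx(1.0, abs=1e-9)
    assert fractions["promoter"] == 0.5
    with pytest.raises(ValueError):
        distribution([])


@pytest.fixture
def two_strand_annotation():
    gp = GeneModel(gene_id="gplus", chrom="chr1", start=1_000, end=3_000,
                   strand="+", biotype="protein_coding",
                   exons=((1_000, 1_500), (2_500, 3_000)))
    gm = GeneModel(gene_id="gminus", chrom="chr1", start=2_200, end=4_001,
                   strand="-", biotype="lincRNA",
                   exons=((2_200, 2_400), (3_500, 4_001)))
    return AnnotationSet(genes=[gp, gm], chrom_sizes={"chr1": 50_000})


def test_associate_both_strands_with_signed_distances(two_strand_annotation):
    """TSSs at 1000 (+) and 4000 (-), summit 2000: both genes associate with
    distances +1000 and -2000 (sign = summit - TSS on the forward axis)."""
    peak = _peak_at(2_000)
    assocs = {a.strand: a for a in associate_peak(peak, two_strand_annotation)}
    assert assocs["+"].gene_id == "gplus" and assocs["+"].distance == 1_000
    assert assocs["-"].gene_id == "gminus" and assocs["-"].distance == -2_000
    anns = annotate_peaks([peak], two_strand_annotation)
    assert sorted(tss_distances(anns)) == [-2_000, 1_000]


def test_associate_outside_window(two_strand_annotation):
    assert associate_peak(_peak_at(18_000), two_strand_annotation) == []


def test_associate_most_proximal_per_strand():
    genes = [
        GeneModel(gene_id="near", chrom="chr1", start=1_000, end=1_800, strand="+",
                  biotype="protein_coding", exons=((1_000, 1_800),)),
        GeneModel(gene_id="far", chrom="chr1", start=3_000, end=3_800, strand="+",
                  biotype="protein_coding", exons=((3_000, 3_800),)),
    ]
    ann = AnnotationSet(genes=genes, chrom_sizes={"chr1": 10_000})
    assocs = associate_peak(_peak_at(200), ann)
    assert [a.gene_id for a in assocs] == ["near"]


def test_associate_tie_broken_lexicographically():
    genes = [
        GeneModel(gene_id="zeta", chrom="chr1", start=1_000, end=1_500, strand="+",
                  biotype="protein_coding", exons=((1_000, 1_500),)),
        GeneModel(gene_id="alpha", chrom="chr1", start=3_000, end=3_500, strand="+",
                  biotype="protein_coding", exons=((3_000, 3_500),)),
    ]
    ann = AnnotationSet(genes=genes, chrom_sizes={"chr1": 10_000})
    assocs = associate_peak(_peak_at(2_000), ann)  # 1000 bp from both TSSs
    assert [a.gene_id for a in assocs] == ["alpha"]


def test_associate_matches_brute_force_oracle():
    """Indexed association equals a full scan over all genes, across 1000
    seeded random summits; at most one gene per strand."""
    ann = make_genome(150, 4_500_000, seed=13)
    rng = np.random.default_rng(13)
    chrom_len = ann.chrom_sizes["chr1"]
    for summit in rng.integers(600, chrom_len - 600, size=1000):
        peak = _peak_at(int(summit))
        got = {a.strand: (a.gene_id, a.distance) for a in associate_peak(peak, ann)}
        assert len(got) <= 2
        assert got == oracle_associations(peak, ann)


def test_call_lincs_recovers_planted_subset():
    """149 specific lincRNAs, 11 of them given a nearby peak: exactly those
    11 are called, each with its peak count."""
    ann = make_genome(160, 6_000_000, seed=21, lincrna_fraction=1.0)
    gene_ids = sorted(g.gene_id for g in ann.genes)
    lincES = set(gene_ids[:149])
    chosen = gene_ids[5:149:13][:11]
    assert len(chosen) == 11
    by_id = ann.by_id()
    peaks = []
    for gid in chosen:
        tss = by_id[gid].tss
        peaks.append(Peak(chrom="chr1", start=tss + 1_900, end=tss + 2_100,
                          summit=tss + 2_000))
    # peaks near genes outside the specific set must not contribute
    outsider = by_id[gene_ids[155]]
    peaks.append(Peak(chrom="chr1", start=outsider.tss + 100,
                      end=outsider.tss + 300, summit=outsider.tss + 200))
    called = call_lincS(peaks, ann, lincES)
    assert set(called) == set(chosen)
    assert all(count == 1 for count in called.values())


def test_call_lincs_window_boundary():
    ann = make_genome(20, 900_000, seed=3, lincrna_fraction=1.0)
    gene = ann.genes[0]
    near = Peak(chrom="chr1", start=gene.tss + 1_900, end=gene.tss + 2_100,
                summit=gene.tss + 2_000)
    far = Peak(chrom="chr1", start=gene.tss + 5_900, end=gene.tss + 6_100,
               summit=gene.tss + 6_000)
    lincES = {gene.gene_id}
    assert set(call_lincS([near], ann, lincES)) == {gene.gene_id}
    assert call_lincS([far], ann, lincES) == {}
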