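"""Promoter windows, the random-peak null and the one-sided Fisher test."""
import math

import numpy as np
import pytest

from stemlinc import (
    AnnotationSet,
    GeneModel,
    Peak,
    fisher_one_sided,
    make_genome,
    overlap_counts,
    promoter_windows,
    random_peaks,
    enrichment_scatter,
    gene_set_enrichment,
)
from conftest import oracle_fisher_greater


def _gene(gid, tss, strand, biotype="protein_coding"):
    if strand == "+":
        start, end = tss, tss + 2_000
    else:
        start, end = tss - 1_999, tss + 1
    return GeneModel(gene_id=gid, chrom="chr1", start=start, end=end,
                     strand=strand, biotype=biotype, exons=((start, end),))


def test_promoter_window_definitions():
    """1 kb upstream of the TSS, on the gene's transcriptional orientation."""
    ann = AnnotationSet(
        genes=[_gene("plus", 5_000, "+"), _gene("minus", 5_000, "-"),
               _gene("linc", 20_000, "+", biotype="lincRNA")],
        chrom_sizes={"chr1": 50_000},
    )
    wins = promoter_windows(ann, upstream=1_000, downstream=0)
    assert wins["plus"] == ("chr1", 4_000, 5_000)
    assert wins["minus"] == ("chr1", 5_001, 6_001)
    assert "linc" not in wins  # biotype filter


def test_random_peaks_conserve_count_and_widths():
    rng = np.random.default_rng(0)
    peaks = []
    for _ in range(100):
        start = int(rng.integers(0, 900_000))
        width = int(rng.integers(200, 501))
        peaks.append(Peak("chr1", start, start + width, start + width // 2))
    shuffled = random_peaks(peaks, {"chr1": 1_000_000, "chr2": 500_000}, seed=3)
    assert len(shuffled) == 100
    assert sorted(p.width for p in shuffled) == sorted(p.width for p in peaks)
    again = random_peaks(peaks, {"chr1": 1_000_000, "chr2": 500_000}, seed=3)
    assert shuffled == again
    with pytest.raises(ValueError, match="wider"):
        random_peaks([Peak("chr1", 0, 5_000, 100)], {"chr1": 2_000}, seed=0)


def test_random_peaks_null_hit_rate_matches_binomial_oracle():
    """Promoter hits by shuffled peaks match the uniform-placement
    expectation: a window of width w is hit by a peak of width v with
    probability ~(w + v - 1)/L.  Totals over 50 seeds within 3 SD."""
    ann = make_genome(40, 1_600_000, seed=5, lincrna_fraction=0.0)
    wins = promoter_windows(ann)
    gene_set = set(wins)
    L = ann.chrom_sizes["chr1"]
    width = 300
    n_peaks = 60
    peaks = [Peak("chr1", s, s + width, s + width // 2)
             for s in range(0, n_peaks * 1_000, 1_000)]
    p_win = [1.0 - (1.0 - (hi - lo + width - 1) / L) ** n_peaks
             for (_, lo, hi) in wins.values()]
    n_seeds = 50
    expected = n_seeds * sum(p_win)
    sd = math.sqrt(n_seeds * sum(p * (1 - p) for p in p_win))
    total = 0
    for seed in range(n_seeds):
        shuffled = random_peaks(peaks, ann.chrom_sizes, seed=seed)
        a, _ = overlap_counts(shuffled, wins, gene_set)
        total += a
    assert abs(total - expected) <= 3 * sd


def test_overlap_counts_boundary_semantics():
    wins = {"g1": ("chr1", 1_000, 2_000), "g2": ("chr1", 5_000, 6_000)}
    inside = Peak("chr1", 1_200, 1_300, 1_250)
    touching = Peak("chr1", 2_000, 2_100, 2_050)  # half-open: no overlap
    assert overlap_counts([inside], wins, {"g1", "g2"}) == (1, 1)
    assert overlap_counts([touching], wins, {"g1", "g2"}) == (0, 2)
    # two peaks in the same promoter count the gene once
    assert overlap_counts([inside, Peak("chr1", 1_400, 1_500, 1_450)],
                          wins, {"g1", "g2"}) == (1, 1)
    # genes without a window are excluded from both counts
    assert overlap_counts([inside], wins, {"g1", "g2", "ghost"}) == (1, 1)


def test_fisher_known_tables():
    assert fisher_one_sided([[0, 5], [2, 3]]).p_one_sided == pytest.approx(1.0)
    r = fisher_one_sided([[5, 5], [1, 9]])
    assert r.p_one_sided == pytest.approx(2730 / 38760, abs=1e-12)
    assert r.odds == pytest.approx(9.0)
    r = fisher_one_sided([[10, 0], [0, 10]])
    assert r.p_one_sided == pytest.approx(1 / math.comb(20, 10), rel=1e-9)
    assert math.isinf(r.odds)
    with pytest.raises(ValueError):
        fisher_one_sided([[-1, 2], [3, 4]])


def test_fisher_matches_enumeration_small_sweep():
    """Implementation equals exact integer enumeration for all tables with
    N <= 20 (the N <= 60 sweep runs in the acceptance suite)."""
    for n in range(1, 21):
        for row in range(n + 1):
            for col in range(n + 1):
                for a in range(max(0, row + col - n), min(row, col) + 1):
                    b, c = row - a, col - a
                    d = n - row - col + a
                    got = fisher_one_sided([[a, b], [c, d]]).p_one_sided
                    assert abs(got - oracle_fisher_greater(a, b, c, d)) < 1e-12


def test_fisher_null_calibration():
    """Under a true null the one-sided p is super-uniform: empirical type-I
    error at alpha in {0.05, 0.01} stays within binomial slack of nominal
    over 1000 simulated tables."""
    rng = np.random.default_rng(99)
    n_genes, p0 = 40, 0.25
    pvals = []
    for _ in range(1000):
        a = rng.binomial(n_genes, p0)
        c = rng.binomial(n_genes, p0)
        pvals.append(fisher_one_sided([[a, n_genes - a], [c, n_genes - c]]).p_one_sided)
    pvals = np.asarray(pvals)
    for alpha in (0.05, 0.01):
        slack = 3 * math.sqrt(alpha * (1 - alpha) / len(pvals))
        assert (pvals <= alpha).mean() <= alpha + slack


def test_enrichment_scatter_flags():
    from stemlinc import FisherResult
    strong = FisherResult(a=16, b=4, c=1, d=19, odds=76.0, p_one_sided=1e-6)
    null = FisherResult(a=5, b=15, c=5, d=15, odds=1.0, p_one_sided=1.0)
    table = enrichment_scatter({"hot": strong, "cold": null},
                               odds_min=2, logp_min=3)
    assert bool(table.loc["hot", "enriched"]) is True
    assert bool(table.loc["cold", "enriched"]) is False  # p=1 never enriched
    everything = enrichment_scatter({"hot": strong, "cold": null},
                                    odds_min=0, logp_min=0)
    assert everything["enriched"].all()


def test_planted_enrichment_detected():
    """A TF hitting 80% of gene-set promoters versus a sparse background is
    flagged at (odds >= 2, -log10 p >= 3)."""
    ann = make_genome(60, 2_400_000, seed=8, lincrna_fraction=0.0)
    wins = promoter_windows(ann)
    genes = sorted(wins)[:20]
    peaks = []
    for gid in genes[:16]:
        _, lo, hi = wins[gid]
        peaks.append(Peak("chr1", lo + 100, lo + 400, lo + 250))
    result = gene_set_enrichment(peaks, wins, set(genes), ann.chrom_sizes, seed=2)
    table = enrichment_scatter({"TF": result}, odds_min=2, logp_min=3)
    assert bool(table.loc["TF", "enriched"]) is True
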