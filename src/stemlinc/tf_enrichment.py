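"""Promoter-binding enrichment of a transcription factor at a gene set.

The question: do a TF's ChIP peaks hit the promoters of a gene set (e.g.
genes downregulated after sponge silencing) more often than random peaks
would?  Promoters are 1 kb windows upstream of protein-coding TSSs by
default; the null is a length-preserving uniform re-placement of the peaks
across the genome; the test is a one-sided Fisher exact test on the 2x2
table (gene-set promoters hit / not hit, by real / random peaks).
"""
from __future__ import annotations

import logging
import math
from typing import Dict, Iterable, List, Mapping, Sequence, Set, Tuple

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats

from .models import AnnotationSet, FisherResult, Peak

logger = logging.getLogger(__name__)

PromoterWindows = Dict[str, Tuple[str, int, int]]  # gene -> (chrom, start, end)


def promoter_windows(
    genes: AnnotationSet,
    upstream: int = 1000,
    downstream: int = 0,
    biotype: str = "protein_coding",
) -> PromoterWindows:
    """One stranded half-open window per gene of ``biotype``:
    [TSS - upstream, TSS + downstream) in the gene's transcriptional
    orientation, expressed on the forward axis."""
    windows: PromoterWindows = {}
    for g in genes:
        if biotype is not None and g.biotype != biotype:
            continue
        if g.strand == "+":
            lo, hi = g.tss - upstream, g.tss + downstream
        else:
            # upstream lies to the right of a minus-strand TSS
            lo, hi = g.tss - downstream + 1, g.tss + upstream + 1
        if hi > lo:
            windows[g.gene_id] = (g.chrom, lo, hi)
    return windows


def random_peaks(peaks: Sequence[Peak], chrom_sizes: Mapping[str, int], seed: int) -> List[Peak]:
    """Length-preserving uniform re-placement of a peak set.

    Each peak keeps its width and is dropped uniformly at random on a
    chromosome chosen proportional to its length (among chromosomes it
    fits on); the summit keeps its relative offset within the peak.
    """
    rng = np.random.default_rng(seed)
    chroms = list(chrom_sizes)
    sizes = np.array([chrom_sizes[c] for c in chroms], dtype=float)
    out: List[Peak] = []
    for p in peaks:
        fits = sizes >= p.width
        if not fits.any():
            raise ValueError(f"peak of width {p.width} wider than every chromosome")
        weights = np.where(fits, sizes, 0.0)
        weights = weights / weights.sum()
        ci = int(rng.choice(len(chroms), p=weights))
        start = int(rng.integers(0, chrom_sizes[chroms[ci]] - p.width + 1))
        out.append(Peak(chrom=chroms[ci], start=start, end=start + p.width,
                        summit=start + (p.summit - p.start), score=p.score))
    return out


def overlap_counts(
    peaks: Sequence[Peak],
    windows: PromoterWindows,
    gene_set: Set[str],
) -> Tuple[int, int]:
    """(a, b): gene-set promoters overlapped by >= 1 bp of any peak, and the
    rest.  Genes without a window are warned about and excluded."""
    trees: Dict[str, IntervalTree] = {}
    for p in peaks:
        trees.setdefault(p.chrom, IntervalTree()).addi(p.start, p.end)
    a = 0
    total = 0
    for gene in sorted(gene_set):
        win = windows.get(gene)
        if win is None:
            logger.warning("gene %s has no promoter window; excluded", gene)
            continue
        total += 1
        chrom, lo, hi = win
        if trees.get(chrom, IntervalTree()).overlap(lo, hi):
            a += 1
    return a, total - a


def fisher_one_sided(table: Sequence[Sequence[int]]) -> FisherResult:
    """One-sided (enrichment) Fisher exact test on a 2x2 table
    [[a, b], [c, d]]: p = P(A >= a) under the hypergeometric null with the
    margins fixed.  Odds = (a*d)/(b*c), infinite when b*c == 0 and a*d > 0."""
    (a, b), (c, d) = table
    for x in (a, b, c, d):
        if x < 0 or int(x) != x:
            raise ValueError("table entries must be non-negative integers")
    a, b, c, d = int(a), int(b), int(c), int(d)
    _, p = stats.fisher_exact([[a, b], [c, d]], alternative="greater")
    if b * c == 0:
        odds = math.inf if a * d > 0 else math.nan
    else:
        odds = (a * d) / (b * c)
    return FisherResult(a=a, b=b, c=c, d=d, odds=odds, p_one_sided=float(p))


def gene_set_enrichment(
    peaks: Sequence[Peak],
    windows: PromoterWindows,
    gene_set: Set[str],
    chrom_sizes: Mapping[str, int],
    seed: int,
) -> FisherResult:
    """Real-vs-random 2x2 test for one TF's peak set at a gene set's
    promoters, with the null row computed from one seeded shuffle."""
    a, b = overlap_counts(peaks, windows, gene_set)
    shuffled = random_peaks(peaks, chrom_sizes, seed)
    c, d = overlap_counts(shuffled, windows, gene_set)
    return fisher_one_sided([[a, b], [c, d]])


def enrichment_scatter(
    results: Mapping[str, FisherResult],
    odds_min: float,
    logp_min: float,
) -> pd.DataFrame:
    """Per-TF summary table with the enriched flag.

    A TF is enriched when odds >= odds_min and -log10 p >= logp_min — the
    'top right corner' rule.  Thresholds are mandatory; there are no
    defaults to pretend otherwise.
    """
    rows = []
    for tf, r in results.items():
        neglog = -math.log10(r.p_one_sided) if r.p_one_sided > 0 else math.inf
        rows.append({
            "tf": tf,
            "odds": r.odds,
            "p_one_sided": r.p_one_sided,
            "neg_log10_p": neglog,
            "intersection_size": r.intersection_size,
            "enriched": bool(r.odds >= odds_min and neglog >= logp_min),
        })
    return pd.DataFrame(rows).set_index("tf")


def benjamini_hochberg(pvalues: Iterable[float]) -> List[float]:
    """Optional multiple-TF correction (not applied by default)."""
    return list(stats.false_discovery_control(np.asarray(list(pvalues))))
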