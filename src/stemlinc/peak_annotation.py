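"""Peak categorization, peak-to-gene association and lincS calling.

Category calls are made on the peak summit — the point of maximal binding
evidence — with precedence promoter > exon > first intron > other intron >
distal intergenic.  The promoter is a configurable window around the TSS
(default +/-1 kb, strand-aware); the first intron is the 5'-most intron on
the gene's strand.  Association links a peak to the gene with the most
proximal TSS on each strand independently, within +/-5 kb of the summit;
distances are signed as summit - TSS on the forward genomic axis.
"""
from __future__ import annotations

import logging
from bisect import bisect_left
from collections import Counter
from typing import Dict, Iterable, List, Sequence, Set, Tuple

from intervaltree import IntervalTree

from .models import AnnotationSet, GeneAssociation, Peak, PeakAnnotation

logger = logging.getLogger(__name__)


class GenomeIndex:
    """Interval indexes over an annotation for summit category queries and
    nearest-TSS lookups."""

    def __init__(self, annotation: AnnotationSet, promoter_up: int = 1000,
                 promoter_down: int = 1000):
        self.annotation = annotation
        self.promoter_up = promoter_up
        self.promoter_down = promoter_down
        self._promoters: Dict[str, IntervalTree] = {}
        self._exons: Dict[str, IntervalTree] = {}
        self._first_introns: Dict[str, IntervalTree] = {}
        self._other_introns: Dict[str, IntervalTree] = {}
        self._tss: Dict[Tuple[str, str], List[Tuple[int, str]]] = {}
        for gene in annotation.genes:
            if gene.strand == "+":
                lo, hi = gene.tss - promoter_up, gene.tss + promoter_down + 1
            else:
                lo, hi = gene.tss - promoter_down, gene.tss + promoter_up + 1
            if hi > lo:
                self._promoters.setdefault(gene.chrom, IntervalTree()).addi(lo, hi, gene)
            for exon in gene.exons:
                self._exons.setdefault(gene.chrom, IntervalTree()).addi(*exon, gene)
            introns = gene.introns_5prime_order()
            for idx, intron in enumerate(introns):
                tree = self._first_introns if idx == 0 else self._other_introns
                tree.setdefault(gene.chrom, IntervalTree()).addi(*intron, gene)
            self._tss.setdefault((gene.chrom, gene.strand), []).append((gene.tss, gene.gene_id))
        for key in self._tss:
            self._tss[key].sort()

    def category(self, peak: Peak) -> str:
        if peak.chrom not in self.annotation.chrom_sizes:
            raise ValueError(f"unknown chromosome {peak.chrom!r}")
        pos = peak.summit
        if self._promoters.get(peak.chrom, IntervalTree()).overlaps(pos):
            return "promoter"
        exon_hits = self._exons.get(peak.chrom, IntervalTree())[pos]
        if exon_hits:
            host = min(exon_hits, key=lambda iv: iv.data.gene_id).data
            return "exon_coding" if host.biotype == "protein_coding" else "exon_noncoding"
        if self._first_introns.get(peak.chrom, IntervalTree()).overlaps(pos):
            return "first_intron"
        if self._other_introns.get(peak.chrom, IntervalTree()).overlaps(pos):
            return "other_intron"
        return "distal_intergenic"

    def nearest_tss(self, chrom: str, strand: str, pos: int,
                    window: int) -> List[Tuple[int, str]]:
        """Genes on one strand whose TSS is within ``window`` of ``pos``,
        closest |distance| first, ties broken by lexicographic gene ID."""
        entries = self._tss.get((chrom, strand), [])
        if not entries:
            return []
        lo = bisect_left(entries, (pos - window,))
        hi = bisect_left(entries, (pos + window + 1,))
        near = [(tss, gid) for tss, gid in entries[lo:hi] if abs(pos - tss) <= window]
        near.sort(key=lambda t: (abs(pos - t[0]), t[1]))
        return near


def categorize_peak(peak: Peak, annotation: AnnotationSet | GenomeIndex,
                    promoter_up: int = 1000, promoter_down: int = 1000) -> str:
    """Genomic category of one peak, decided by its summit position."""
    index = annotation if isinstance(annotation, GenomeIndex) else GenomeIndex(
        annotation, promoter_up, promoter_down)
    return index.category(peak)


def associate_peak(peak: Peak, annotation: AnnotationSet | GenomeIndex,
                   window: int = 5000) -> List[GeneAssociation]:
    """Up to two gene associations: the most TSS-proximal gene on each
    strand within ``window`` bp of the summit."""
    index = annotation if isinstance(annotation, GenomeIndex) else GenomeIndex(annotation)
    out: List[GeneAssociation] = []
    for strand in ("+", "-"):
        near = index.nearest_tss(peak.chrom, strand, peak.summit, window)
        if near:
            if len(near) > 1 and abs(peak.summit - near[0][0]) == abs(peak.summit - near[1][0]):
                logger.info(
                    "peak %s:%d tie on strand %s between %s and %s; keeping %s",
                    peak.chrom, peak.summit, strand, near[0][1], near[1][1], near[0][1])
            tss, gene_id = near[0]
            out.append(GeneAssociation(gene_id=gene_id, distance=peak.summit - tss,
                                       strand=strand))
    return out


def annotate_peaks(peaks: Sequence[Peak], annotation: AnnotationSet,
                   promoter_up: int = 1000, promoter_down: int = 1000,
                   window: int = 5000) -> List[PeakAnnotation]:
    """Categorize and associate a peak collection with one shared index."""
    index = GenomeIndex(annotation, promoter_up, promoter_down)
    return [
        PeakAnnotation(peak=p, category=index.category(p),
                       associated_genes=associate_peak(p, index, window))
        for p in peaks
    ]


def distribution(annotations: Sequence[PeakAnnotation]) -> Dict[str, float]:
    """Fraction of peaks per category; fractions sum to 1."""
    if not annotations:
        raise ValueError("no peak annotations")
    counts = Counter(a.category for a in annotations)
    n = len(annotations)
    return {cat: c / n for cat, c in sorted(counts.items())}


def tss_distances(annotations: Iterable[PeakAnnotation]) -> List[int]:
    """One signed summit-to-TSS distance per (peak, associated gene)."""
    return [assoc.distance for a in annotations for assoc in a.associated_genes]


def call_lincS(peaks: Sequence[Peak], annotation: AnnotationSet,
               lincES: Set[str], window: int = 5000) -> Dict[str, int]:
    """Focal-TF-bound subset of the specific lincRNA set.

    Returns the lincES genes having at least one peak whose summit lies
    within ``window`` bp of their TSS, mapped to their peak count.
    """
    index = GenomeIndex(annotation)
    counts: Counter = Counter()
    for peak in peaks:
        for assoc in associate_peak(peak, index, window):
            if assoc.gene_id in lincES:
                counts[assoc.gene_id] += 1
    return dict(counts)
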