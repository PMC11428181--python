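"""Core domain types shared across the pipeline.

All genomic coordinates are 0-based half-open on the forward strand,
regardless of the dialect they were read from (GTF is converted on input).
The TSS of a minus-strand gene is therefore ``genomic end - 1``.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd

BIOTYPES = ("protein_coding", "lincRNA", "other_noncoding")

PEAK_CATEGORIES = (
    "promoter",
    "exon_coding",
    "exon_noncoding",
    "first_intron",
    "other_intron",
    "distal_intergenic",
)


@dataclass(frozen=True)
class GeneModel:
    """A stranded, multi-exon gene: the unit of association and category calls.

    ``exons`` are 0-based half-open intervals sorted by genomic start and
    non-overlapping.  ``tss`` is the start of the 5'-most exon on the gene's
    strand (end - 1 for minus-strand genes).
    """

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str
    biotype: str
    exons: Tuple[Tuple[int, int], ...]

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: strand must be '+' or '-'")
        if self.biotype not in BIOTYPES:
            raise ValueError(f"gene {self.gene_id}: unknown biotype {self.biotype!r}")
        if not self.exons:
            raise ValueError(f"gene {self.gene_id}: gene needs at least one exon")
        for s, e in self.exons:
            if not (self.start <= s < e <= self.end):
                raise ValueError(f"gene {self.gene_id}: exon ({s},{e}) outside gene body")

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end - 1

    @property
    def introns(self) -> Tuple[Tuple[int, int], ...]:
        """Intervals between consecutive exons, in genomic order."""
        ex = sorted(self.exons)
        return tuple((ex[i][1], ex[i + 1][0]) for i in range(len(ex) - 1))

    def introns_5prime_order(self) -> Tuple[Tuple[int, int], ...]:
        """Introns ordered from the gene's 5' end (first intron first)."""
        iv = self.introns
        return iv if self.strand == "+" else tuple(reversed(iv))


@dataclass
class AnnotationSet:
    """A collection of gene models plus chromosome lengths.

    Conceptually this is the merged annotation the pipeline consumes; the
    merging itself happens upstream and is not modelled here.
    """

    genes: List[GeneModel]
    chrom_sizes: Dict[str, int]

    def __post_init__(self) -> None:
        seen: Set[str] = set()
        for g in self.genes:
            if g.gene_id in seen:
                raise ValueError(f"duplicate gene ID {g.gene_id!r}")
            seen.add(g.gene_id)
            size = self.chrom_sizes.get(g.chrom)
            if size is None:
                raise ValueError(f"gene {g.gene_id}: unknown chromosome {g.chrom!r}")
            if not (0 <= g.start < g.end <= size):
                raise ValueError(
                    f"gene {g.gene_id}: coordinates ({g.start},{g.end}) exceed "
                    f"{g.chrom} length {size}"
                )

    def __len__(self) -> int:
        return len(self.genes)

    def __iter__(self):
        return iter(self.genes)

    def by_id(self) -> Dict[str, GeneModel]:
        return {g.gene_id: g for g in self.genes}


@dataclass(frozen=True)
class Peak:
    """A ChIP interval with a single-base summit (start <= summit < end)."""

    chrom: str
    start: int
    end: int
    summit: int
    score: Optional[float] = None

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"peak {self.chrom}:{self.start}-{self.end}: start >= end")
        if not (self.start <= self.summit < self.end):
            raise ValueError(
                f"peak {self.chrom}:{self.start}-{self.end}: summit {self.summit} "
                "outside interval"
            )

    @property
    def width(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class GeneAssociation:
    """One peak-to-gene link: signed distance is summit - TSS on the forward axis."""

    gene_id: str
    distance: int
    strand: str


@dataclass
class PeakAnnotation:
    """A peak with its genomic category and up to two associated genes
    (the most TSS-proximal gene on each strand within the window)."""

    peak: Peak
    category: str
    associated_genes: List[GeneAssociation] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.category not in PEAK_CATEGORIES:
            raise ValueError(f"unknown peak category {self.category!r}")
        if len(self.associated_genes) > 2:
            raise ValueError("a peak associates with at most two genes")
        strands = [a.strand for a in self.associated_genes]
        if len(strands) != len(set(strands)):
            raise ValueError("at most one associated gene per strand")


class ExpressionMatrix:
    """A genes x samples FPKM matrix with one sample flagged as the focal
    condition (the ES-cell sample in the original design)."""

    def __init__(self, data: pd.DataFrame, focal_sample: str):
        if focal_sample not in data.columns:
            raise ValueError(f"focal sample {focal_sample!r} not in sample columns")
        values = data.to_numpy(dtype=float)
        if np.isnan(values).any():
            raise ValueError("expression matrix contains missing values")
        if (values < 0).any():
            raise ValueError("negative expression values are not allowed")
        if data.index.has_duplicates:
            raise ValueError("duplicate gene IDs in expression matrix")
        self.data = data.astype(float)
        self.focal_sample = focal_sample

    @property
    def gene_ids(self) -> List[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> List[str]:
        return list(self.data.columns)

    @property
    def focal(self) -> pd.Series:
        return self.data[self.focal_sample]

    @property
    def nonfocal(self) -> pd.DataFrame:
        return self.data.drop(columns=[self.focal_sample])

    def subset(self, gene_ids: Sequence[str]) -> "ExpressionMatrix":
        return ExpressionMatrix(self.data.loc[list(gene_ids)], self.focal_sample)

    def __len__(self) -> int:
        return len(self.data)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"ExpressionMatrix({len(self.data)} genes x {len(self.data.columns)} "
            f"samples, focal={self.focal_sample!r})"
        )


@dataclass(frozen=True)
class MiRNA:
    """A mature miRNA; seeds are exact substrings of the mature sequence
    (positions 2-8 and 2-7, 1-based as conventionally numbered)."""

    name: str
    mature: str

    def __post_init__(self) -> None:
        seq = self.mature.upper().replace("T", "U")
        if len(seq) < 8:
            raise ValueError(f"miRNA {self.name}: mature sequence shorter than 8 nt")
        bad = set(seq) - set("ACGU")
        if bad:
            raise ValueError(f"miRNA {self.name}: invalid characters {sorted(bad)}")
        object.__setattr__(self, "mature", seq)

    @property
    def seed_2_8(self) -> str:
        return self.mature[1:8]

    @property
    def seed_2_7(self) -> str:
        return self.mature[1:7]


@dataclass(frozen=True)
class MreSite:
    """One seed-match occurrence.  ``t1`` is the 0-based coordinate of the
    target nucleotide opposite miRNA position 1 — the 3'-most base of the
    site.  For a 7mer-m8 flush with the sequence end, t1 equals the sequence
    length (no position-1 base exists)."""

    mirna_name: str
    t1: int
    site_class: str

    def __post_init__(self) -> None:
        if self.site_class not in ("8mer-1a", "7mer-m8", "7mer-1a"):
            raise ValueError(f"unknown site class {self.site_class!r}")


@dataclass(frozen=True)
class EnrichmentResult:
    """Upper-tail Poisson probability of seeing >= observed_k sites in a
    sequence of length_kb given a background rate of lambda_per_kb."""

    observed_k: int
    length_kb: float
    lambda_per_kb: float
    p_value: float
    log10_p: float


@dataclass(frozen=True)
class CernaScore:
    """Susceptibility of one mRNA to expression fluctuations of the sponge
    lncRNA, summed over the miRNA families they share."""

    mrna_id: str
    shared_families: frozenset
    score: float
    rank: Optional[int] = None


@dataclass(frozen=True)
class FisherResult:
    """A 2x2 enrichment test: gene-set promoters hit / not hit by real
    vs. random peaks, with the one-sided (enrichment) Fisher p."""

    a: int
    b: int
    c: int
    d: int
    odds: float
    p_one_sided: float

    @property
    def intersection_size(self) -> int:
        return self.a

    @property
    def table(self) -> Tuple[Tuple[int, int], Tuple[int, int]]:
        return ((self.a, self.b), (self.c, self.d))
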