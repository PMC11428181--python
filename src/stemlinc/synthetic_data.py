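"""Generators for every pipeline input, with known ground truth.

Each generator is a pure function of its arguments including the seed, so
fixtures are reproducible and every downstream stage can be tested against
planted truth without any external download.

The expression generator emulates a tissue atlas (one ES-like focal sample
plus many somatic tissues) with a log-normal FPKM background and a small
planted set of focal-condition-specific genes.  The sequence generators
plant strict seed sites at controlled positions on a background that has
been scrubbed of accidental matches, so a scan recovers exactly the planted
architecture.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, FrozenSet, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .models import AnnotationSet, ExpressionMatrix, GeneModel, MiRNA, MreSite, Peak
from .mre_analysis import revcomp_rna, scan_sites, site_patterns

# Mature sequences of the two microRNA families whose response elements the
# sponge architecture is built around (miRBase, mmu).
MIR128_3P = MiRNA(name="miR-128-3p", mature="UCACAGUGAACCGGUCUCUUU")
MIR138_5P = MiRNA(name="miR-138-5p", mature="AGCUGGUGUUGUGAAUCAGGCCG")

_BASES = np.array(list("ACGU"))


@dataclass(frozen=True)
class AtlasTruth:
    """Ground truth of a synthetic expression atlas."""

    specific_gene_ids: FrozenSet[str]
    fold: float
    noise_sd: float


# ---------------------------------------------------------------------------
# expression atlas
# ---------------------------------------------------------------------------

def make_atlas(
    n_genes: int,
    n_tissues: int,
    n_specific: int,
    fold: float,
    noise_sd: float,
    seed: int,
    meanlog: float = 1.0,
    sdlog: float = 1.0,
    off_meanlog: float = -1.5,
    focal_sample: str = "ESC",
) -> Tuple[ExpressionMatrix, AtlasTruth]:
    """Simulate a genes x samples FPKM atlas with planted specific genes.

    Background genes draw i.i.d. log-normal(meanlog, sdlog) FPKM in every
    sample.  Planted genes are true single-condition genes: their off-state
    baseline is log-normal(off_meanlog, noise_sd) — below the FPKM-1
    detection threshold — in every sample, and the focal sample is
    multiplied by ``fold``.  At fold == 1 a planted gene therefore shows no
    focal elevation at all.
    """
    if n_tissues < 2:
        raise ValueError("need at least 2 samples")
    if n_specific > n_genes:
        raise ValueError("n_specific cannot exceed n_genes")
    if fold <= 0:
        raise ValueError("fold must be positive")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    rng = np.random.default_rng(seed)
    gene_ids = [f"gene_{i:05d}" for i in range(n_genes)]
    samples = [focal_sample] + [f"tissue_{j:02d}" for j in range(1, n_tissues)]
    values = rng.lognormal(mean=meanlog, sigma=sdlog, size=(n_genes, n_tissues))
    specific_idx = rng.choice(n_genes, size=n_specific, replace=False)
    off = rng.lognormal(mean=off_meanlog, sigma=noise_sd, size=(n_specific, n_tissues))
    values[specific_idx, :] = off
    values[specific_idx, 0] *= fold
    df = pd.DataFrame(values, index=gene_ids, columns=samples)
    truth = AtlasTruth(
        specific_gene_ids=frozenset(gene_ids[i] for i in specific_idx),
        fold=fold,
        noise_sd=noise_sd,
    )
    return ExpressionMatrix(df, focal_sample), truth


# ---------------------------------------------------------------------------
# genome annotation
# ---------------------------------------------------------------------------

def make_genome(
    n_genes: int,
    chrom_length: int,
    seed: int,
    lincrna_fraction: float = 0.5,
    chrom: str = "chr1",
    min_gap: int = 12_000,
) -> AnnotationSet:
    """Generate stranded multi-exon genes on one chromosome.

    Adjacent gene bodies are separated by at least ``min_gap`` bp (default
    12 kb) so the +/-5 kb peak-to-gene association rule has unambiguous
    truth.  Each gene has 2-6 exons; biotypes are drawn protein_coding /
    lincRNA at ``lincrna_fraction``.
    """
    rng = np.random.default_rng(seed)
    n_exons = rng.integers(2, 7, size=n_genes)
    structures = []
    lengths = []
    for k in n_exons:
        exon_sizes = rng.integers(150, 601, size=k)
        intron_sizes = rng.integers(300, 1501, size=k - 1)
        structures.append((exon_sizes, intron_sizes))
        lengths.append(int(exon_sizes.sum() + intron_sizes.sum()))
    required = sum(lengths) + (n_genes + 1) * min_gap
    if required > chrom_length:
        raise ValueError(
            f"insufficient space: {n_genes} genes need >= {required} bp, "
            f"chromosome is {chrom_length} bp"
        )
    leftover = chrom_length - required
    extra = rng.multinomial(leftover, np.full(n_genes + 1, 1.0 / (n_genes + 1)))
    genes: List[GeneModel] = []
    pos = 0
    for i in range(n_genes):
        pos += min_gap + int(extra[i])
        exon_sizes, intron_sizes = structures[i]
        exons = []
        cursor = pos
        for j, size in enumerate(exon_sizes):
            exons.append((cursor, cursor + int(size)))
            cursor += int(size)
            if j < len(intron_sizes):
                cursor += int(intron_sizes[j])
        strand = "+" if rng.random() < 0.5 else "-"
        biotype = "lincRNA" if rng.random() < lincrna_fraction else "protein_coding"
        genes.append(
            GeneModel(
                gene_id=f"gene_{i + 1:04d}",
                chrom=chrom,
                start=pos,
                end=cursor,
                strand=strand,
                biotype=biotype,
                exons=tuple(exons),
            )
        )
        pos = cursor
    return AnnotationSet(genes=genes, chrom_sizes={chrom: chrom_length})


# ---------------------------------------------------------------------------
# peaks with known category composition
# ---------------------------------------------------------------------------

_CATEGORY_ALIASES = {"distal": "distal_intergenic", "intergenic": "distal_intergenic"}


def _subtract(interval: Tuple[int, int], windows: Sequence[Tuple[int, int]]) -> List[Tuple[int, int]]:
    """Remove half-open windows from a half-open interval."""
    pieces = [interval]
    for lo, hi in windows:
        nxt: List[Tuple[int, int]] = []
        for s, e in pieces:
            if hi <= s or lo >= e:
                nxt.append((s, e))
                continue
            if s < lo:
                nxt.append((s, lo))
            if hi < e:
                nxt.append((hi, e))
        pieces = nxt
    return [(s, e) for s, e in pieces if e > s]


def _promoter_interval(gene: GeneModel, up: int, down: int) -> Tuple[int, int]:
    """Positions whose summit is classified promoter, half-open, strand-aware."""
    if gene.strand == "+":
        return gene.tss - up, gene.tss + down + 1
    return gene.tss - down, gene.tss + up + 1


def make_peaks(
    annotation: AnnotationSet,
    proportions: Dict[str, float],
    n_peaks: int,
    seed: int,
    promoter_up: int = 1000,
    promoter_down: int = 1000,
    width_range: Tuple[int, int] = (200, 500),
    genes: Optional[Sequence[str]] = None,
) -> Tuple[List[Peak], List[str]]:
    """Place peak summits inside regions of known genomic category.

    ``proportions`` maps category to fraction (must sum to 1); categories are
    the six summit categories, plus the aliases ``distal`` and ``exon`` (an
    exon of either biotype, with the truth label recording the host gene's
    split).  Peak widths are drawn uniformly from ``width_range`` and the
    summit is placed uniformly within the peak.  ``genes`` optionally
    restricts gene-anchored categories to a subset of gene IDs.

    Returns (peaks, truth_categories) in parallel order.
    """
    total = sum(proportions.values())
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"proportions sum to {total}, expected 1")
    rng = np.random.default_rng(seed)
    allowed = set(genes) if genes is not None else None

    def usable(g: GeneModel) -> bool:
        return allowed is None or g.gene_id in allowed

    chrom_len = {c: n for c, n in annotation.chrom_sizes.items()}
    margin = max(width_range[1], 500)
    promoter_windows: Dict[str, List[Tuple[int, int]]] = {}
    for g in annotation.genes:
        promoter_windows.setdefault(g.chrom, []).append(
            _promoter_interval(g, promoter_up, promoter_down)
        )

    def clip(chrom: str, pieces: List[Tuple[int, int]]) -> List[Tuple[int, int]]:
        lo, hi = margin, chrom_len[chrom] - margin
        return [(max(s, lo), min(e, hi)) for s, e in pieces if min(e, hi) > max(s, lo)]

    # candidate summit regions per category, as (chrom, start, end, truth)
    regions: Dict[str, List[Tuple[str, int, int, str]]] = {
        "promoter": [], "exon_coding": [], "exon_noncoding": [], "exon": [],
        "first_intron": [], "other_intron": [], "distal_intergenic": [],
    }
    for g in annotation.genes:
        if not usable(g):
            continue
        own = [_promoter_interval(g, promoter_up, promoter_down)]
        for s, e in clip(g.chrom, [own[0]]):
            regions["promoter"].append((g.chrom, s, e, "promoter"))
        exon_truth = "exon_coding" if g.biotype == "protein_coding" else "exon_noncoding"
        for exon in g.exons:
            for s, e in clip(g.chrom, _subtract(exon, own)):
                regions[exon_truth].append((g.chrom, s, e, exon_truth))
                regions["exon"].append((g.chrom, s, e, exon_truth))
        introns = g.introns_5prime_order()
        for idx, intron in enumerate(introns):
            cat = "first_intron" if idx == 0 else "other_intron"
            for s, e in clip(g.chrom, _subtract(intron, own)):
                regions[cat].append((g.chrom, s, e, cat))
    # intergenic space minus every promoter window
    for chrom, size in chrom_len.items():
        bodies = sorted((g.start, g.end) for g in annotation.genes if g.chrom == chrom)
        gaps = []
        prev = 0
        for s, e in bodies:
            if s > prev:
                gaps.append((prev, s))
            prev = max(prev, e)
        if prev < size:
            gaps.append((prev, size))
        for gap in gaps:
            for s, e in clip(chrom, _subtract(gap, promoter_windows.get(chrom, []))):
                regions["distal_intergenic"].append((chrom, s, e, "distal_intergenic"))

    # integer counts by largest remainder
    cats = list(proportions)
    raw = {c: proportions[c] * n_peaks for c in cats}
    counts = {c: int(math.floor(raw[c])) for c in cats}
    short = n_peaks - sum(counts.values())
    for c in sorted(cats, key=lambda c: (-(raw[c] - counts[c]), c))[:short]:
        counts[c] += 1

    peaks: List[Peak] = []
    truths: List[str] = []
    for cat in cats:
        key = _CATEGORY_ALIASES.get(cat, cat)
        pool = regions.get(key)
        if pool is None:
            raise ValueError(f"unknown peak category {cat!r}")
        if counts[cat] and not pool:
            raise ValueError(f"no available region for category {cat!r}")
        weights = np.array([e - s for _, s, e, _ in pool], dtype=float)
        weights /= weights.sum()
        for _ in range(counts[cat]):
            chrom, s, e, truth = pool[rng.choice(len(pool), p=weights)]
            summit = int(rng.integers(s, e))
            width = int(rng.integers(width_range[0], width_range[1] + 1))
            offset = int(rng.integers(0, width))
            start = summit - offset
            peaks.append(Peak(chrom=chrom, start=start, end=start + width, summit=summit))
            truths.append(truth)
    return peaks, truths


# ---------------------------------------------------------------------------
# sequences with planted seed sites
# ---------------------------------------------------------------------------

def _footprint(t1: int, site_class: str) -> Tuple[int, int]:
    # 8 bases up to and including t1: the literal plus anchor/guard position
    return max(t1 - 7, 0), t1 + 1


def _scrub(seq: np.ndarray, mirnas: Sequence[MiRNA], rng: np.random.Generator,
           protected: Sequence[Tuple[int, int]] = ()) -> None:
    """Resample windows until no 2-7 core match remains outside protected
    footprints.  Every strict site class contains the 2-7 core, so removing
    cores removes all classes."""
    cores = [site_patterns(m)[1] for m in mirnas]
    for _ in range(10_000):
        text = "".join(seq)
        hit = None
        for core in cores:
            i = text.find(core)
            while i != -1:
                if not any(lo <= i and i + 6 <= hi for lo, hi in protected):
                    free = [j for j in range(i, i + 6)
                            if not any(lo <= j < hi for lo, hi in protected)]
                    if free:
                        hit = free
                        break
                i = text.find(core, i + 1)
            if hit:
                break
        if hit is None:
            return
        seq[hit] = rng.choice(_BASES, size=len(hit))
    raise RuntimeError("scrubbing did not converge")


def make_sponge_transcript(
    length: int,
    plants: Sequence[Tuple[MiRNA, Sequence[int], str]],
    seed: int,
    scrub_mirnas: Sequence[MiRNA] = (),
) -> Tuple[str, List[MreSite]]:
    """Build an RNA sequence with exactly the requested seed sites.

    ``plants`` is a list of (miRNA, t1 positions, site class); background is
    uniform over {A,C,G,U}, scrubbed of accidental matches for all planted
    and ``scrub_mirnas`` families, then the site literals are written.  The
    output is verified by re-scanning: the recovered sites equal the planted
    ones exactly, with junction artefacts resampled away.
    """
    rng = np.random.default_rng(seed)
    planted: List[MreSite] = []
    footprints: List[Tuple[int, int]] = []
    for mirna, positions, site_class in plants:
        if site_class not in ("8mer-1a", "7mer-m8", "7mer-1a"):
            raise ValueError(f"unknown site class {site_class!r}")
        for t1 in positions:
            min_t1 = 6 if site_class == "7mer-1a" else 7
            if not (min_t1 <= t1 < length):
                raise ValueError(f"t1 {t1} out of bounds for class {site_class}")
            planted.append(MreSite(mirna_name=mirna.name, t1=t1, site_class=site_class))
            footprints.append(_footprint(t1, site_class))
    footprints_sorted = sorted(footprints)
    for (s1, e1), (s2, e2) in zip(footprints_sorted, footprints_sorted[1:]):
        if s2 < e1:
            raise ValueError("overlapping planted sites")

    all_mirnas = list({m.name: m for m, _, _ in plants}.values())
    for m in scrub_mirnas:
        if m.name not in {x.name for x in all_mirnas}:
            all_mirnas.append(m)
    seq = rng.choice(_BASES, size=length)
    _scrub(seq, all_mirnas, rng)

    for mirna, positions, site_class in plants:
        match_2_8, core_2_7, anchor = site_patterns(mirna)
        for t1 in positions:
            if site_class in ("8mer-1a", "7mer-m8"):
                seq[t1 - 7 : t1] = list(match_2_8)
                if site_class == "8mer-1a":
                    seq[t1] = "A"
                else:
                    seq[t1] = rng.choice([b for b in "CGU"])
            else:  # 7mer-1a
                seq[t1 - 6 : t1] = list(core_2_7)
                seq[t1] = "A"
                if t1 >= 7:
                    seq[t1 - 7] = rng.choice([b for b in "ACGU" if b != anchor])

    expected = {(s.mirna_name, s.t1, s.site_class) for s in planted}
    for _ in range(100):
        text = "".join(seq)
        found = {
            (s.mirna_name, s.t1, s.site_class)
            for m in all_mirnas
            for s in scan_sites(text, m)
        }
        if found == expected:
            return text, sorted(planted, key=lambda s: (s.mirna_name, s.t1))
        missing = expected - found
        if missing:  # a plant was clobbered: should not happen
            raise RuntimeError(f"planted sites lost during generation: {missing}")
        fixed_any = False
        for name, t1, cls in found - expected:
            span = range(max(t1 - 7, 0), min(t1 + 1, length))
            free = [j for j in span if not any(lo <= j < hi for lo, hi in footprints)]
            if free:
                seq[free] = rng.choice(_BASES, size=len(free))
                fixed_any = True
        if not fixed_any:
            break
    raise RuntimeError("could not remove accidental sites without touching plants")


def make_mre_sequence(
    length: int,
    mirna: MiRNA,
    t1_positions: Sequence[int],
    site_class: str,
    seed: int,
) -> Tuple[str, List[MreSite]]:
    """Single-miRNA convenience wrapper around :func:`make_sponge_transcript`."""
    return make_sponge_transcript(length, [(mirna, list(t1_positions), site_class)], seed)


def make_background_transcriptome(
    n_sequences: int, length: int, seed: int
) -> List[str]:
    """Plain uniform-random RNA sequences (not scrubbed): a neutral
    transcriptome whose seed-match density defines the background rate."""
    rng = np.random.default_rng(seed)
    return ["".join(rng.choice(_BASES, size=length)) for _ in range(n_sequences)]


def make_lncenc1_like(seed: int = 0) -> Tuple[str, Dict[str, MiRNA], List[MreSite]]:
    """Synthetic stand-in for the Lncenc1 sponge transcript.

    A 3.3 kb synthetic RNA carrying the reported response-element
    architecture of the real transcript: 22 miR-128-3p sites (21 of them
    7mer-m8, 20 on an exact 22-nt spacing grid) and 17 miR-138-5p sites
    (12 8mer-1a plus 5 7mer-1a).  Constructed from scratch; only the site
    architecture, not the underlying sequence, mirrors the real locus.
    """
    run = [100 + 22 * i for i in range(20)]  # the regularly spaced block
    plants = [
        (MIR128_3P, run + [600], "7mer-m8"),  # 21 7mer-m8 sites
        (MIR128_3P, [645], "8mer-1a"),        # the single non-7mer-m8 site
        (MIR138_5P, [800 + 45 * j for j in range(12)], "8mer-1a"),
        (MIR138_5P, [1400 + 45 * j for j in range(5)], "7mer-1a"),
    ]
    seq, planted = make_sponge_transcript(3300, plants, seed)
    return seq, {MIR128_3P.name: MIR128_3P, MIR138_5P.name: MIR138_5P}, planted


# ---------------------------------------------------------------------------
# ceRNA triples with known sharing structure
# ---------------------------------------------------------------------------

def _random_mirnas(n: int, rng: np.random.Generator) -> List[MiRNA]:
    """Draw random mature miRNAs whose seed cores are mutually distinct and
    do not occur inside each other's 2-8 match literals."""
    mirnas: List[MiRNA] = []
    for i in range(n):
        for _ in range(1000):
            mature = "".join(rng.choice(_BASES, size=21))
            cand = MiRNA(name=f"miR-S{i + 1:02d}", mature=mature)
            core = revcomp_rna(cand.seed_2_7)
            m28 = revcomp_rna(cand.seed_2_8)
            clash = False
            for other in mirnas:
                o_core = revcomp_rna(other.seed_2_7)
                o_m28 = revcomp_rna(other.seed_2_8)
                if core in o_m28 or o_core in m28 or core == o_core:
                    clash = True
                    break
            if not clash:
                mirnas.append(cand)
                break
        else:
            raise RuntimeError("could not draw non-clashing miRNA seeds")
    return mirnas


def make_cerna_system(
    n_mrnas: int,
    n_mirnas: int,
    sharing: Optional[Dict[str, FrozenSet[str]]] = None,
    expr_ranges: Optional[Dict[str, Tuple[float, float]]] = None,
    seed: int = 0,
    lnc_id: str = "LNC1",
) -> Tuple[Dict[str, str], Dict[str, MiRNA], ExpressionMatrix, Dict[str, FrozenSet[str]]]:
    """Generate a sponge lncRNA, mRNA 3'UTRs and miRNA families with known
    MRE sharing structure plus a single-condition expression table.

    The lncRNA carries one site for every family; each mRNA UTR carries one
    site per family in its ``sharing`` entry.  The default sharing is nested
    (mRNA 1 shares the most families, the last shares one), which fixes the
    expected susceptibility ranking whatever the expression draws are.

    Returns (sequences, mirnas, expression, truth_sharing) where sequences
    holds the lncRNA and UTR sequences keyed by ID.
    """
    rng = np.random.default_rng(seed)
    mirnas = _random_mirnas(n_mirnas, rng)
    names = [m.name for m in mirnas]
    if sharing is None:
        sharing = {}
        for i in range(n_mrnas):
            k = max(n_mirnas - i, 1)
            sharing[f"mRNA_{i + 1:02d}"] = frozenset(names[:k])
    else:
        for mrna, fams in sharing.items():
            unknown = set(fams) - set(names)
            if unknown:
                raise ValueError(f"unknown miRNA families {sorted(unknown)} for {mrna}")
    by_name = {m.name: m for m in mirnas}
    sequences: Dict[str, str] = {}
    lnc_plants = [(by_name[name], [100 + 80 * i], "7mer-m8") for i, name in enumerate(names)]
    lnc_len = 300 + 80 * n_mirnas
    seq, _ = make_sponge_transcript(lnc_len, lnc_plants, int(rng.integers(2**31)),
                                    scrub_mirnas=mirnas)
    sequences[lnc_id] = seq
    for mrna, fams in sharing.items():
        fams_sorted = sorted(fams)
        plants = [(by_name[name], [100 + 80 * i], "7mer-m8") for i, name in enumerate(fams_sorted)]
        utr_len = 300 + 80 * max(len(fams_sorted), 1)
        seq, _ = make_sponge_transcript(utr_len, plants, int(rng.integers(2**31)),
                                        scrub_mirnas=mirnas)
        sequences[mrna] = seq
    ranges = {"lnc": (10.0, 50.0), "mrna": (10.0, 50.0), "mirna": (10.0, 50.0)}
    if expr_ranges:
        ranges.update(expr_ranges)
    rows = {lnc_id: rng.uniform(*ranges["lnc"])}
    for mrna in sharing:
        rows[mrna] = rng.uniform(*ranges["mrna"])
    for name in names:
        rows[name] = rng.uniform(*ranges["mirna"])
    expr = ExpressionMatrix(pd.DataFrame({"mESC": rows}), focal_sample="mESC")
    return sequences, by_name, expr, dict(sharing)
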