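"""Readers and writers for the standard formats the pipeline touches.

Dialect handling: GTF/GFF3 coordinates (1-based closed) are converted to the
internal 0-based half-open convention on read; BED-family inputs are already
0-based half-open.  All validation errors name the offending line.
"""
from __future__ import annotations

import logging
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Tuple

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .models import BIOTYPES, AnnotationSet, ExpressionMatrix, GeneModel, Peak

logger = logging.getLogger(__name__)


class ParseError(ValueError):
    """A malformed record; the message carries the file line number."""


_BIOTYPE_ALIASES = {
    "protein_coding": "protein_coding",
    "lincrna": "lincRNA",
    "lincRNA": "lincRNA",
    "other_noncoding": "other_noncoding",
}


def normalize_biotype(raw: Optional[str]) -> Tuple[str, bool]:
    """Map an annotation biotype onto the fixed three-way vocabulary.

    Returns (biotype, recognized).  Anything outside the vocabulary collapses
    to ``other_noncoding`` — the category scheme only distinguishes coding,
    lincRNA and other non-coding loci.
    """
    if raw is None:
        return "other_noncoding", False
    key = raw.strip()
    if key in _BIOTYPE_ALIASES:
        return _BIOTYPE_ALIASES[key], True
    if key.lower() in _BIOTYPE_ALIASES:
        return _BIOTYPE_ALIASES[key.lower()], True
    return "other_noncoding", False


def _parse_gtf_attributes(text: str) -> Dict[str, str]:
    attrs: Dict[str, str] = {}
    for chunk in text.strip().rstrip(";").split(";"):
        chunk = chunk.strip()
        if not chunk:
            continue
        if "=" in chunk and '"' not in chunk:  # GFF3 style key=value
            key, _, value = chunk.partition("=")
            attrs[key.strip()] = value.strip()
        else:  # GTF style key "value"
            key, _, value = chunk.partition(" ")
            attrs[key.strip()] = value.strip().strip('"')
    return attrs


def read_annotation(
    path: str | Path,
    biotype_key: str = "gene_biotype",
    chrom_sizes: Optional[Dict[str, int]] = None,
    biotypes: Optional[Dict[str, str]] = None,
) -> AnnotationSet:
    """Read a GTF/GFF3 or BED12 annotation into an :class:`AnnotationSet`.

    One :class:`GeneModel` is built per gene ID from its exon features; the
    TSS is the start of the 5'-most exon on the gene's strand.  Records
    without a strand are rejected (logged and counted).  ``biotypes`` lets the
    caller supply per-gene biotypes for formats that carry none (BED12).
    If ``chrom_sizes`` is omitted, each chromosome's length is taken as the
    right-most annotated coordinate.
    """
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix == ".bed":
        genes = _read_bed12(path, biotypes or {})
    else:
        genes = _read_gtf(path, biotype_key, biotypes or {})
    if chrom_sizes is None:
        chrom_sizes = {}
        for g in genes:
            chrom_sizes[g.chrom] = max(chrom_sizes.get(g.chrom, 0), g.end)
    return AnnotationSet(genes=genes, chrom_sizes=chrom_sizes)


def _read_gtf(path: Path, biotype_key: str, biotype_override: Dict[str, str]) -> List[GeneModel]:
    exons: Dict[str, List[Tuple[int, int]]] = {}
    meta: Dict[str, Tuple[str, str]] = {}  # gene -> (chrom, strand)
    biotype_raw: Dict[str, Optional[str]] = {}
    gene_lines_seen: set = set()
    rejected = 0
    unrecognized = 0
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 9:
                raise ParseError(f"{path.name} line {lineno}: expected 9 tab-separated fields")
            chrom, _, ftype, start_s, end_s, _, strand, _, attr_text = fields
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise ParseError(f"{path.name} line {lineno}: non-integer coordinates") from exc
            if start < 1 or end < start:
                raise ParseError(f"{path.name} line {lineno}: invalid coordinates {start}-{end}")
            attrs = _parse_gtf_attributes(attr_text)
            gene_id = attrs.get("gene_id") or attrs.get("ID") or attrs.get("Parent")
            if gene_id is None:
                raise ParseError(f"{path.name} line {lineno}: no gene_id attribute")
            if ftype == "gene":
                if gene_id in gene_lines_seen:
                    raise ParseError(f"{path.name} line {lineno}: duplicate gene ID {gene_id!r}")
                gene_lines_seen.add(gene_id)
            if ftype not in ("gene", "exon"):
                continue
            if strand not in ("+", "-"):
                rejected += 1
                logger.warning("%s line %d: missing strand, record rejected", path.name, lineno)
                continue
            if gene_id in meta and meta[gene_id] != (chrom, strand):
                raise ParseError(
                    f"{path.name} line {lineno}: duplicate gene ID {gene_id!r} "
                    "on a different chromosome or strand"
                )
            meta[gene_id] = (chrom, strand)
            if biotype_key in attrs or gene_id not in biotype_raw:
                biotype_raw[gene_id] = attrs.get(biotype_key, biotype_raw.get(gene_id))
            if ftype == "exon":
                # GTF 1-based closed -> 0-based half-open
                exons.setdefault(gene_id, []).append((start - 1, end))
    if rejected:
        logger.info("%s: %d strandless records rejected", path.name, rejected)
    genes: List[GeneModel] = []
    for gene_id, (chrom, strand) in meta.items():
        ex = sorted(set(exons.get(gene_id, [])))
        if not ex:
            continue
        if gene_id in biotype_override:
            biotype, ok = biotype_override[gene_id], True
        else:
            biotype, ok = normalize_biotype(biotype_raw.get(gene_id))
        if not ok:
            unrecognized += 1
        genes.append(
            GeneModel(
                gene_id=gene_id,
                chrom=chrom,
                start=ex[0][0],
                end=ex[-1][1],
                strand=strand,
                biotype=biotype,
                exons=tuple(ex),
            )
        )
    if unrecognized:
        logger.info("%s: %d genes with unrecognized biotype mapped to other_noncoding",
                    path.name, unrecognized)
    return genes


def _read_bed12(path: Path, biotypes: Dict[str, str]) -> List[GeneModel]:
    genes: List[GeneModel] = []
    seen: set = set()
    rejected = 0
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 12:
                raise ParseError(f"{path.name} line {lineno}: BED12 needs 12 fields")
            chrom, start_s, end_s, name, _, strand = fields[:6]
            start, end = int(start_s), int(end_s)
            if strand not in ("+", "-"):
                rejected += 1
                logger.warning("%s line %d: missing strand, record rejected", path.name, lineno)
                continue
            if name in seen:
                raise ParseError(f"{path.name} line {lineno}: duplicate gene ID {name!r}")
            seen.add(name)
            block_count = int(fields[9])
            sizes = [int(x) for x in fields[10].rstrip(",").split(",")]
            starts = [int(x) for x in fields[11].rstrip(",").split(",")]
            if len(sizes) != block_count or len(starts) != block_count:
                raise ParseError(f"{path.name} line {lineno}: block fields disagree with blockCount")
            exons = tuple((start + s, start + s + sz) for s, sz in zip(starts, sizes))
            genes.append(
                GeneModel(
                    gene_id=name,
                    chrom=chrom,
                    start=start,
                    end=end,
                    strand=strand,
                    biotype=biotypes.get(name, "other_noncoding"),
                    exons=exons,
                )
            )
    if rejected:
        logger.info("%s: %d strandless records rejected", path.name, rejected)
    return genes


def write_annotation(annotation: AnnotationSet, path: str | Path) -> None:
    """Write an AnnotationSet as GTF (gene + exon lines, gene_biotype attr)."""
    path = Path(path)
    with open(path, "w") as out:
        for g in annotation.genes:
            attrs = f'gene_id "{g.gene_id}"; gene_biotype "{g.biotype}";'
            out.write(
                f"{g.chrom}\tstemlinc\tgene\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\t{attrs}\n"
            )
            for s, e in g.exons:
                out.write(
                    f"{g.chrom}\tstemlinc\texon\t{s + 1}\t{e}\t.\t{g.strand}\t.\t{attrs}\n"
                )


def read_peaks(path: str | Path) -> List[Peak]:
    """Read BED3/BED6/narrowPeak intervals into :class:`Peak` objects.

    narrowPeak column 10 (summit offset) >= 0 sets summit = start + offset;
    otherwise the summit defaults to the interval midpoint (floor).  Records
    with start >= end are rejected and counted.
    """
    path = Path(path)
    peaks: List[Peak] = []
    rejected = 0
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path.name} line {lineno}: need at least 3 BED fields")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ParseError(f"{path.name} line {lineno}: non-integer coordinates") from exc
            if start >= end:
                rejected += 1
                logger.warning("%s line %d: start >= end, record rejected", path.name, lineno)
                continue
            score: Optional[float] = None
            if len(fields) >= 5 and fields[4] not in (".", ""):
                try:
                    score = float(fields[4])
                except ValueError:
                    score = None
            summit = (start + end) // 2
            if len(fields) >= 10:  # narrowPeak
                try:
                    offset = int(fields[9])
                except ValueError:
                    offset = -1
                if offset >= 0:
                    summit = start + offset
            peaks.append(Peak(chrom=chrom, start=start, end=end, summit=summit, score=score))
    if rejected:
        logger.info("%s: %d malformed intervals rejected", path.name, rejected)
    if not peaks:
        logger.warning("%s: no peaks read", path.name)
    return peaks


def write_peaks(peaks: Iterable[Peak], path: str | Path) -> None:
    """Write peaks in narrowPeak format (summit as the offset column)."""
    with open(path, "w") as out:
        for i, p in enumerate(peaks):
            score = p.score if p.score is not None else 0
            out.write(
                f"{p.chrom}\t{p.start}\t{p.end}\tpeak_{i}\t{score}\t.\t0\t-1\t-1\t{p.summit - p.start}\n"
            )


def read_expression(path: str | Path, focal_sample: str) -> ExpressionMatrix:
    """Read a TSV FPKM matrix (gene IDs in the first column, samples in the
    header) and flag ``focal_sample`` as the focal condition."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    try:
        return ExpressionMatrix(df, focal_sample)
    except ValueError as exc:
        raise ValueError(f"{Path(path).name}: {exc}") from exc


def write_expression(matrix: ExpressionMatrix, path: str | Path) -> None:
    matrix.data.to_csv(path, sep="\t")


def read_fasta(path: str | Path) -> Dict[str, str]:
    """Read FASTA into {id: sequence}, transcribing DNA to RNA (T -> U)."""
    return {
        rec.id: str(rec.seq).upper().replace("T", "U")
        for rec in SeqIO.parse(str(path), "fasta")
    }


def write_fasta(sequences: Dict[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()]
    SeqIO.write(records, str(path), "fasta")
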