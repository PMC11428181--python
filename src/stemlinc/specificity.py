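"""Expression-specificity scoring and selection of focal-condition genes.

The specificity measure (SPM) of gene g in sample i is the cosine between
the gene's cross-sample expression vector X and the ideal one-hot profile
for sample i:

    SPM_i = x_i / ||X||_2,    so that  sum_i SPM_i^2 = 1.

A gene expressed in exactly one sample scores 1 there and 0 elsewhere; a
uniformly expressed gene scores 1/sqrt(n) everywhere.  Genes are first
filtered on abundance (max FPKM >= 1 by default), scored, split by k-means
on the focal-sample SPM, and the high-centroid cluster is reduced to the
final specific set by a detection rule: expressed in the focal sample and
in at most one other tissue.
"""
from __future__ import annotations

import logging
from typing import Optional, Set, Tuple

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .models import ExpressionMatrix
from .synthetic_data import AtlasTruth

logger = logging.getLogger(__name__)


def filter_expressed(matrix: ExpressionMatrix, min_fpkm: float = 1.0) -> ExpressionMatrix:
    """Keep genes whose maximum FPKM across samples reaches ``min_fpkm``.

    Gene order is preserved; an empty result is allowed (and logged).
    """
    keep = matrix.data.max(axis=1) >= min_fpkm
    if not keep.any():
        logger.warning("no genes reach FPKM %.3g in any sample", min_fpkm)
    return ExpressionMatrix(matrix.data.loc[keep], matrix.focal_sample)


def spm_scores(matrix: ExpressionMatrix) -> pd.DataFrame:
    """Per-gene SPM across samples: x_i / ||X||_2, all-zero genes score 0."""
    values = matrix.data.to_numpy(dtype=float)
    norms = np.sqrt((values**2).sum(axis=1))
    safe = np.where(norms > 0, norms, 1.0)
    spm = values / safe[:, None]
    spm[norms == 0] = 0.0
    return pd.DataFrame(spm, index=matrix.data.index, columns=matrix.data.columns)


def specificity_table(matrix: ExpressionMatrix) -> pd.DataFrame:
    """SPM scores plus a ``focal_spm`` column for the focal sample."""
    spm = spm_scores(matrix)
    table = spm.copy()
    table["focal_spm"] = spm[matrix.focal_sample]
    return table


def cluster_specific(
    results: pd.DataFrame,
    k: int = 2,
    seed: int = 0,
    on: str = "focal_spm",
) -> pd.DataFrame:
    """k-means split of the (1-D by default) specificity scores.

    Uses k-means++ with 10 restarts at a fixed seed; the cluster whose
    centroid is highest is flagged ``is_specific``.  ``on`` may name any
    column (or list of columns) should clustering on the full SPM vector be
    preferred over the focal-sample score.
    """
    if k > len(results):
        raise ValueError(f"k={k} exceeds the {len(results)} available genes")
    values = results[on].to_numpy(dtype=float)
    if values.ndim == 1:
        values = values[:, None]
    if np.allclose(values, values[0]):
        raise ValueError("no separation: all specificity scores are identical")
    km = KMeans(n_clusters=k, init="k-means++", n_init=10, random_state=seed)
    labels = km.fit_predict(values)
    high = int(np.argmax(km.cluster_centers_.mean(axis=1)))
    out = results.copy()
    out["cluster"] = labels
    out["is_specific"] = labels == high
    return out


def select_lincES(
    results: pd.DataFrame,
    matrix: ExpressionMatrix,
    max_other_tissues: int = 1,
    min_fpkm: float = 1.0,
) -> Set[str]:
    """The focal-specific gene set: high-centroid cluster members that are
    detected (FPKM >= min_fpkm) in the focal sample and in at most
    ``max_other_tissues`` non-focal samples."""
    if "is_specific" not in results:
        raise ValueError("run cluster_specific first")
    candidates = results.index[results["is_specific"]]
    data = matrix.data.loc[candidates]
    focal_ok = data[matrix.focal_sample] >= min_fpkm
    others = data.drop(columns=[matrix.focal_sample])
    n_detected = (others >= min_fpkm).sum(axis=1)
    selected = candidates[(focal_ok & (n_detected <= max_other_tissues)).to_numpy()]
    return set(selected)


def recover_truth(selected: Set[str], truth: AtlasTruth) -> Tuple[float, float]:
    """(sensitivity, precision) of a selected set against planted truth."""
    truth_set = set(truth.specific_gene_ids)
    tp = len(selected & truth_set)
    sensitivity = tp / len(truth_set) if truth_set else 0.0
    precision = tp / len(selected) if selected else 0.0
    return sensitivity, precision


def run_specificity(
    matrix: ExpressionMatrix,
    min_fpkm: float = 1.0,
    k: int = 2,
    seed: int = 0,
    max_other_tissues: int = 1,
    gene_subset: Optional[Set[str]] = None,
) -> Tuple[Set[str], pd.DataFrame]:
    """Full pipeline: abundance filter -> SPM -> k-means -> detection rule.

    ``gene_subset`` restricts the analysis to e.g. the lincRNA biotype.
    Returns the selected gene set and the per-gene table.
    """
    if gene_subset is not None:
        keep = [g for g in matrix.gene_ids if g in gene_subset]
        matrix = matrix.subset(keep)
    expressed = filter_expressed(matrix, min_fpkm=min_fpkm)
    table = specificity_table(expressed)
    table = cluster_specific(table, k=k, seed=seed)
    selected = select_lincES(table, expressed, max_other_tissues=max_other_tissues,
                             min_fpkm=min_fpkm)
    table["selected"] = table.index.isin(selected)
    return selected, table
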