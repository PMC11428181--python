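"""Shared fixtures and independent oracles used across the suite.

The oracles deliberately re-derive results by brute force (window
enumeration, exhaustive threshold search, integer hypergeometric tails)
so they share no code path with the implementation they check.
"""
from __future__ import annotations

import math
from typing import Dict, List, Sequence, Tuple

import numpy as np
import pytest

from stemlinc import MIR128_3P, MIR138_5P, AnnotationSet, MiRNA, Peak


@pytest.fixture
def mir128() -> MiRNA:
    return MIR128_3P


@pytest.fixture
def mir138() -> MiRNA:
    return MIR138_5P


_COMP = {"A": "U", "C": "G", "G": "C", "U": "A"}


def oracle_scan(seq: str, mirna: MiRNA) -> List[Tuple[int, str]]:
    """Brute-force seed-site enumeration: walk every candidate t1 and test
    the class definitions against reverse-complement literals, char by char.

    Returns sorted (t1, class) tuples."""
    seq = seq.upper().replace("T", "U")
    m8 = "".join(_COMP[b] for b in reversed(mirna.mature[1:8]))
    core = "".join(_COMP[b] for b in reversed(mirna.mature[1:7]))
    n = len(seq)
    out = []
    for t1 in range(n + 1):
        has_m8 = t1 >= 7 and all(seq[t1 - 7 + j] == m8[j] for j in range(7))
        has_core = t1 >= 6 and all(seq[t1 - 6 + j] == core[j] for j in range(6))
        t1_is_a = t1 < n and seq[t1] == "A"
        if has_m8 and t1_is_a:
            out.append((t1, "8mer-1a"))
        elif has_m8:
            out.append((t1, "7mer-m8"))
        elif has_core and t1_is_a:
            out.append((t1, "7mer-1a"))
    return out


def oracle_kmeans2_1d(values: Sequence[float]) -> frozenset:
    """Exhaustive optimal 2-means in one dimension: try every threshold
    between sorted neighbours, minimise total within-cluster sum of squares,
    and return the index set of the high cluster."""
    order = np.argsort(values)
    x = np.asarray(values, dtype=float)[order]
    n = len(x)
    best = (math.inf, None)
    csum = np.cumsum(x)
    csq = np.cumsum(x**2)
    for split in range(1, n):
        left_ss = csq[split - 1] - csum[split - 1] ** 2 / split
        right_n = n - split
        right_sum = csum[-1] - csum[split - 1]
        right_ss = (csq[-1] - csq[split - 1]) - right_sum**2 / right_n
        ss = left_ss + right_ss
        if ss < best[0] - 1e-12:
            best = (ss, split)
    split = best[1]
    return frozenset(int(i) for i in order[split:])


def oracle_fisher_greater(a: int, b: int, c: int, d: int) -> float:
    """Exact upper-tail hypergeometric probability by integer enumeration."""
    m = a + b + c + d
    row = a + b
    col = a + c
    denom = math.comb(m, row)
    hi = min(row, col)
    num = sum(math.comb(col, x) * math.comb(m - col, row - x) for x in range(a, hi + 1))
    return num / denom


def oracle_associations(
    peak: Peak, annotation: AnnotationSet, window: int = 5000
) -> Dict[str, Tuple[str, int]]:
    """Brute-force nearest-TSS scan over all genes: strand -> (gene, distance)."""
    best: Dict[str, Tuple[str, int]] = {}
    for strand in ("+", "-"):
        cands = [
            (abs(peak.summit - g.tss), g.gene_id, peak.summit - g.tss)
            for g in annotation.genes
            if g.chrom == peak.chrom and g.strand == strand
            and abs(peak.summit - g.tss) <= window
        ]
        if cands:
            cands.sort()
            best[strand] = (cands[0][1], cands[0][2])
    return best


def random_rna(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list("ACGU"), size=length))
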