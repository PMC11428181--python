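"""Strict canonical miRNA seed-site scanning, Poisson enrichment and spacing.

Site geometry follows the canonical seed-match classes.  Target position 1
(t1) is the base opposite miRNA position 1, i.e. the 3'-most base of a site;
target positions 2..8 run 5'-ward from it and pair with miRNA seed positions
2..8.  The three strict classes are:

* ``8mer-1a``  — perfect match to miRNA positions 2-8 plus an A at t1;
* ``7mer-m8``  — perfect match to positions 2-8, t1 base not an A (the class
  partition keeps every locus in exactly one class);
* ``7mer-1a``  — perfect match to positions 2-7 plus an A at t1, only when
  the position-8 extension fails.

G:U wobbles and 3' supplementary pairing are deliberately not considered:
only strict Watson-Crick seed matches count.
"""
from __future__ import annotations

import math
from collections import Counter
from typing import Dict, Iterable, List, Sequence, Tuple

from scipy import stats

from .models import EnrichmentResult, MiRNA, MreSite

_RNA_COMPLEMENT = {"A": "U", "C": "G", "G": "C", "U": "A"}


def normalize_rna(sequence: str) -> str:
    """Uppercase and transcribe T -> U; reject anything outside {A,C,G,U}."""
    seq = sequence.upper().replace("T", "U")
    for i, base in enumerate(seq):
        if base not in _RNA_COMPLEMENT:
            raise ValueError(f"invalid character {base!r} at position {i}")
    return seq


def revcomp_rna(sequence: str) -> str:
    return "".join(_RNA_COMPLEMENT[b] for b in reversed(sequence))


def site_patterns(mirna: MiRNA) -> Tuple[str, str, str]:
    """Return (match_2_8, core_2_7, m8_anchor) target-strand literals.

    ``match_2_8`` is the 7-nt reverse complement of seed positions 2-8;
    ``core_2_7`` the 6-nt reverse complement of positions 2-7; ``m8_anchor``
    the single target base that pairs miRNA position 8 (match_2_8 ==
    m8_anchor + core_2_7).
    """
    match_2_8 = revcomp_rna(mirna.seed_2_8)
    core_2_7 = revcomp_rna(mirna.seed_2_7)
    return match_2_8, core_2_7, _RNA_COMPLEMENT[mirna.mature[7]]


def scan_sites(sequence: str, mirna: MiRNA) -> List[MreSite]:
    """Scan an RNA sequence for strict seed sites of one miRNA.

    Returns one :class:`MreSite` per t1 coordinate, carrying the best
    applicable class, sorted by t1.  A 7-nt 2-8 match flush with the 3' end
    of the sequence is reported as 7mer-m8 with t1 == len(sequence).
    """
    seq = normalize_rna(sequence)
    match_2_8, core_2_7, m8_anchor = site_patterns(mirna)
    n = len(seq)
    sites: List[MreSite] = []
    i = seq.find(match_2_8)
    while i != -1:
        t1 = i + 7
        if t1 < n and seq[t1] == "A":
            cls = "8mer-1a"
        else:
            cls = "7mer-m8"
        sites.append(MreSite(mirna_name=mirna.name, t1=t1, site_class=cls))
        i = seq.find(match_2_8, i + 1)
    i = seq.find(core_2_7)
    while i != -1:
        t1 = i + 6
        if t1 < n and seq[t1] == "A" and not (i > 0 and seq[i - 1] == m8_anchor):
            sites.append(MreSite(mirna_name=mirna.name, t1=t1, site_class="7mer-1a"))
        i = seq.find(core_2_7, i + 1)
    sites.sort(key=lambda s: s.t1)
    return sites


def count_by_class(sites: Iterable[MreSite]) -> Dict[str, int]:
    counts = {"8mer-1a": 0, "7mer-m8": 0, "7mer-1a": 0}
    counts.update(Counter(s.site_class for s in sites))
    return counts


def background_lambda(transcriptome: Iterable[str], mirna: MiRNA) -> float:
    """Mean number of strict sites per kilobase over a transcriptome.

    This is the background rate for :func:`poisson_enrichment` — the mean
    site density of the expressed transcript population.
    """
    total_sites = 0
    total_nt = 0
    for seq in transcriptome:
        seq = normalize_rna(seq)
        total_sites += len(scan_sites(seq, mirna))
        total_nt += len(seq)
    if total_nt == 0:
        raise ValueError("transcriptome has zero total length")
    return total_sites / (total_nt / 1000.0)


def poisson_enrichment(observed_k: int, length_kb: float, lambda_per_kb: float) -> EnrichmentResult:
    """Upper-tail Poisson probability P(X >= k) with X ~ Poisson(lambda * L).

    Computed through the survival function in log space so extreme counts
    (p far below float underflow in a naive sum) stay representable via
    ``log10_p``.
    """
    if length_kb <= 0:
        raise ValueError("length_kb must be positive")
    if lambda_per_kb < 0:
        raise ValueError("lambda_per_kb must be non-negative")
    if observed_k < 0:
        raise ValueError("observed_k must be non-negative")
    mu = lambda_per_kb * length_kb
    if mu == 0 and observed_k >= 1:
        raise ValueError("degenerate background: lambda is zero but sites were observed")
    if observed_k == 0:
        p, log10p = 1.0, 0.0
    else:
        logp = stats.poisson.logsf(observed_k - 1, mu)  # P(X >= k) = sf(k-1)
        p = math.exp(logp) if logp > -745 else 0.0
        log10p = logp / math.log(10)
    return EnrichmentResult(
        observed_k=observed_k,
        length_kb=length_kb,
        lambda_per_kb=lambda_per_kb,
        p_value=p,
        log10_p=log10p,
    )


def spacing_regularity(sites: Sequence[MreSite]) -> Tuple[int, int]:
    """Modal spacing between successive sites and the regular-site count.

    Successive t1 differences are computed on the t1-sorted sites; the modal
    spacing is the most frequent difference (ties broken toward the smaller
    value).  A site is regular when the gap to its predecessor equals the
    modal spacing exactly; the first site is regular when the gap to its
    successor does.  No tolerance is applied.
    """
    t1s = sorted(s.t1 for s in sites)
    if len(t1s) < 2:
        raise ValueError("spacing needs at least 2 sites")
    diffs = [b - a for a, b in zip(t1s, t1s[1:])]
    counts = Counter(diffs)
    best = max(counts.values())
    modal = min(d for d, c in counts.items() if c == best)
    regular = sum(1 for d in diffs if d == modal)  # sites regular via their left gap
    if diffs[0] == modal:
        regular += 1  # the first site, anchored by its right gap
    return modal, regular
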