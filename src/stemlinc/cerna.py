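"""Ranking candidate ceRNA (sponge) partner mRNAs of a lncRNA.

A cytoplasmic sponge lncRNA de-represses mRNAs that carry response elements
for the same miRNA families.  For each mRNA sharing at least one family
with the sponge, a susceptibility score aggregates, over the shared
families f:

    score(m) = sum_f  E(miR_f) * n_f(m) * [ n_f(lnc) * E(lnc)
                                            / sum_t n_f(t) * E(t) ]

where n_f(x) is the number of family-f sites on transcript x, E(.) is the
expression level in the focal condition, and the denominator runs over all
expressed transcripts carrying family-f sites (the family's target pool).
The bracketed factor is the sponge's share of the family's expression-
weighted target pool, in (0, 1]; the score grows with miRNA abundance, the
mRNA's site count and the sponge's pool dominance, and vanishes as the
sponge's expression goes to zero.  The scoring function is a plug-in:
alternative susceptibility formulas can be passed to :func:`rank_partners`.

Only transcripts and miRNAs actually expressed in the focal condition
participate (see :func:`expressed_subset`).
"""
from __future__ import annotations

from typing import Callable, Dict, FrozenSet, Iterable, List, Mapping, Set, Tuple

from .models import CernaScore, ExpressionMatrix, MiRNA, MreSite
from .mre_analysis import scan_sites


def expressed_subset(expr: ExpressionMatrix, min_expr: float = 1.0) -> Set[str]:
    """IDs whose focal-sample expression reaches ``min_expr``."""
    focal = expr.focal
    return set(focal.index[focal >= min_expr])


def shared_families(lnc_sites: Iterable[MreSite], utr_sites: Iterable[MreSite]) -> Set[str]:
    """miRNA families with at least one site on both transcripts."""
    return {s.mirna_name for s in lnc_sites} & {s.mirna_name for s in utr_sites}


def site_count_table(
    sequences: Mapping[str, str], mirnas: Mapping[str, MiRNA]
) -> Dict[Tuple[str, str], int]:
    """(transcript, family) -> strict site count, from the scanner."""
    counts: Dict[Tuple[str, str], int] = {}
    for tid, seq in sequences.items():
        for name, mirna in mirnas.items():
            n = len(scan_sites(seq, mirna))
            if n:
                counts[(tid, name)] = n
    return counts


def susceptibility_score(
    mrna_id: str,
    lnc_id: str,
    site_counts: Mapping[Tuple[str, str], int],
    expr: Mapping[str, float],
) -> CernaScore:
    """Score one candidate mRNA against the sponge (formula above).

    ``site_counts`` must already be restricted to expressed transcripts and
    expressed miRNA families.
    """
    families = {f for (tid, f) in site_counts if tid == lnc_id}
    shared = {f for f in families if site_counts.get((mrna_id, f), 0) > 0}
    if not shared:
        raise ValueError(f"{mrna_id} is not a candidate: no family shared with {lnc_id}")
    score = 0.0
    for fam in shared:
        pool = sum(
            n * expr[tid]
            for (tid, f), n in site_counts.items()
            if f == fam and tid in expr
        )
        lnc_weight = site_counts[(lnc_id, fam)] * expr[lnc_id]
        score += expr[fam] * site_counts[(mrna_id, fam)] * (lnc_weight / pool)
    return CernaScore(mrna_id=mrna_id, shared_families=frozenset(shared), score=score)


def rank_candidates(scores: Iterable[CernaScore]) -> List[CernaScore]:
    """Stable descending-score order, ties broken by mRNA ID; ranks 1..n."""
    ordered = sorted(scores, key=lambda s: (-s.score, s.mrna_id))
    return [
        CernaScore(mrna_id=s.mrna_id, shared_families=s.shared_families,
                   score=s.score, rank=i + 1)
        for i, s in enumerate(ordered)
    ]


def rank_partners(
    lnc_id: str,
    sequences: Mapping[str, str],
    mirnas: Mapping[str, MiRNA],
    expr: ExpressionMatrix,
    min_expr: float = 1.0,
    score_fn: Callable[..., CernaScore] = susceptibility_score,
) -> List[CernaScore]:
    """End-to-end partner ranking: scan -> filter to expressed -> score -> rank.

    ``sequences`` maps transcript IDs (the sponge plus candidate mRNA
    3'UTRs) to RNA sequences; miRNA families and transcripts below
    ``min_expr`` in the focal sample are dropped before scoring, so silent
    families can never contribute to a score.
    """
    expressed = expressed_subset(expr, min_expr)
    if lnc_id not in expressed:
        raise ValueError(f"sponge {lnc_id!r} is not expressed in the focal sample")
    seqs = {tid: s for tid, s in sequences.items() if tid in expressed}
    fams = {name: m for name, m in mirnas.items() if name in expressed}
    counts = site_count_table(seqs, fams)
    levels = {tid: float(expr.focal[tid]) for tid in expressed if tid in expr.focal.index}
    scores = []
    lnc_sites = [(f,) for (tid, f) in counts if tid == lnc_id]
    for tid in seqs:
        if tid == lnc_id:
            continue
        if any(counts.get((tid, f), 0) > 0 for (f,) in lnc_sites):
            scores.append(score_fn(tid, lnc_id, counts, levels))
    return rank_candidates(scores)


def sharing_table(truth: Mapping[str, FrozenSet[str]]) -> Dict[str, int]:
    """Convenience: planted sharing cardinality per mRNA."""
    return {m: len(f) for m, f in truth.items()}
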