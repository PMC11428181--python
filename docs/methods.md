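# Methods

This note records the models, defaults and design choices behind each
stage, what the synthetic generators do and do not emulate, and the known
limitations. Nothing here states an empirical result that the test suite
or `scripts/acceptance.py` does not itself compute.

## Coordinates and formats

All internal coordinates are 0-based half-open on the forward genomic
strand. GTF/GFF3 input (1-based closed) is converted on read; BED-family
input passes through unchanged. The TSS of a minus-strand gene is its
genomic `end − 1`; its first intron is the 5′-most intron *on the gene's
strand* (the right-most in genomic order). The biotype vocabulary is fixed
to {protein_coding, lincRNA, other_noncoding}; unrecognized biotypes
collapse to other_noncoding with a logged count, because the category
scheme only distinguishes coding, lincRNA and other non-coding loci.
narrowPeak summits come from column 10 when ≥ 0, otherwise the interval
midpoint (floor). The readers validate records individually: malformed
lines raise errors naming the line number, strandless records are rejected
and counted, and duplicate gene IDs are a hard error.

## Specificity (SPM)

The specificity of gene g in sample i is the cosine between its expression
vector and the one-hot profile of sample i: `SPM_i = x_i / ‖X‖₂`. The
squared-cosine variant is a monotone transform of this score; the pipeline
does not depend on the choice: the raw 2-means boundary can shift for
heavy-tailed background genes (1-D k-means is not monotone-invariant in
general), but every boundary gene fails the downstream detection rule, so
the final selected set is identical under either variant — the test suite
checks this over 20 seeded atlases.

Defaults and rationale:

* abundance filter `min_fpkm = 1.0` — genes never reaching 1 FPKM are
  treated as unexpressed;
* `k = 2` for k-means — the task is a binary specific/non-specific split;
  k-means++ with 10 restarts and a fixed seed for determinism. Clustering
  runs on the 1-D focal-sample SPM (the selection target is focal
  specificity, and 1-D admits an exhaustive threshold-search oracle); the
  `on=` parameter accepts the full SPM vector instead;
* detection rule: FPKM ≥ 1 in the focal sample and in at most
  `max_other_tissues = 1` non-focal samples — "specific with at most one
  other tissue" reuses the abundance threshold as the detection threshold.

Degenerate input (all scores identical) is an error ("no separation")
rather than an arbitrary split.

## Synthetic expression atlas

`make_atlas` draws background FPKM i.i.d. log-normal(meanlog 1, sdlog 1)
per gene and sample — a heavy right tail resembling real FPKM
distributions, all values positive. Planted specific genes are true
single-condition genes: their off-state baseline is
log-normal(−1.5, noise_sd) in every sample — median ≈ 0.22 FPKM, safely
below the detection threshold — and the focal sample is multiplied by
`fold` (default conditions: 2000 genes, 22 samples, 100 planted, fold 10,
noise 0.3). At fold 1 a planted gene has no focal elevation whatsoever.
The generator does not emulate correlated tissues, batch effects,
library-size variation or partially specific genes; passing the recovery
tests therefore shows the selection machinery is correct under its own
model, not that real atlases separate this cleanly.

## Synthetic genome and peaks

`make_genome` places 2–6-exon genes (exons 150–600 bp, introns
300–1500 bp) on one chromosome with ≥ 12 kb between adjacent gene bodies,
so every ±5 kb association has a unique truth; strands are fair coin
flips and biotypes drawn at `lincrna_fraction`. `make_peaks` converts the
requested category proportions to integer counts by largest remainder and
places each summit inside a region of its truth category under the same
promoter definition the annotator uses, sampling regions proportional to
length; widths are 200–500 bp with the summit uniform inside the peak.
Placement is exact by construction, so planted-category recovery is a
self-consistency check of the two codepaths, not a statistical claim.

## Peak categories and association

Categories are decided by the summit alone (the single point of maximal
binding evidence; whole-peak overlap would multiply-assign wide peaks)
with precedence promoter > exon > first intron > other intron > distal
intergenic. The promoter window is TSS ± 1 kb by default and configurable;
no single published figure fixes this choice, so it is exposed rather than
hidden. Association examines each strand independently and keeps the gene
with minimal |summit − TSS| ≤ 5 kb; distances are signed summit − TSS on
the forward axis. Ties are broken toward the lexicographically smaller
gene ID and logged. Gene-body overlap without a nearby TSS does not
associate — association is a TSS-distance concept here.

## Strict seed-site scanning

A site is located by t1, the target base opposite miRNA position 1 (the
3′-most base of the site); this makes the 8mer/7mer variants at one locus
collapse to a single best-class site instead of counting embedded
sub-matches. With `match2-8` the reverse complement of miRNA positions
2–8:

* 8mer-1a: `match2-8` immediately 5′ of an A at t1;
* 7mer-m8: `match2-8` with the t1 base not an A (classes partition loci;
  a match flush with the 3′ end, where no t1 base exists, counts here);
* 7mer-1a: the 2–7 core match plus an A at t1, only when the position-8
  extension fails.

G:U wobble, seed mismatches and 3′ supplementary pairing are deliberately
out of scope — only strict Watson–Crick seed matches count. DNA input is
transcribed T → U on read.

The enrichment statistic is the upper-tail Poisson probability
`P(X ≥ k)`, `X ~ Poisson(λL)`, with λ the mean strict-site density per kb
over a background transcriptome and L the transcript length in kb,
computed through the survival function in log space so extreme counts
remain representable via `log10_p`. λ = 0 with k ≥ 1 is an error
(degenerate background). Whether the background should be whole
transcripts or 3′UTRs only is a data question, not a code one: the
function takes whatever sequence collection the caller supplies.

Spacing regularity computes successive t1 differences, takes the modal
difference (ties toward the smaller value), and counts a site as regular
when its gap to the predecessor equals the modal spacing exactly, plus the
first site when its gap to the successor does. The tolerance is exactly
zero by design; a site whose left gap is broken is irregular even if its
right gap happens to match, which matches hand enumeration of the worked
cases. The sponge-architecture fixture (`make_lncenc1_like`) is a
synthetic 3.3 kb transcript carrying 22 miR-128-3p sites (21 7mer-m8, 20
on an exact 22-nt grid) and 17 miR-138-5p sites (12 8mer-1a, 5 7mer-1a):
the site architecture is planted, the sequence itself is random and
scrubbed, so scanning it is a genuine recovery test, not a lookup.

## Sequence generation and scrubbing

Backgrounds are uniform over {A,C,G,U}. Every strict site class contains
the 2–7 core match, so scrubbing resamples any window containing a core
match for the relevant miRNAs until none remains (windowed resampling
keeps generation O(length); global rejection would not terminate for long
sequences). After planting the site literals, the sequence is re-scanned
and any junction-born accidental site is removed by resampling bases
outside planted footprints; generation fails loudly rather than return a
sequence whose scan differs from the plant list. Planted 7mer-m8 sites
get a non-A t1 base, planted 7mer-1a sites a position-8 guard base, so no
plant can be classified into a different class.

## ceRNA susceptibility score

The score is this package's concrete instantiation of
expression-weighted sponge susceptibility:

    score(m) = Σ_f E(miR_f) · n_f(m) · [ n_f(lnc)·E(lnc) / Σ_t n_f(t)·E(t) ]

over shared families f, with the denominator running over all expressed
transcripts carrying family-f sites. Each factor is testable: the score is
linear in miRNA abundance, monotone in every site count, vanishes with the
sponge's expression, and the pool-share factor lies in (0, 1] with
equality exactly when the sponge is the family's only expressed target.
The scoring function is a plug-in argument to `rank_partners`, so a
different susceptibility formula can be swapped in without touching the
scan/filter/rank scaffolding. Site counts come from this package's own
scanner rather than an external target database, removing
database-version dependence. Transcripts and miRNAs below the expression
threshold in the focal sample are removed before scoring, so silent
families can never contribute. Ties in the ranking are broken by mRNA ID
and the sort is stable. The default synthetic system uses nested sharing
(mRNA 1 shares the most families … the last shares one) because nestedness
fixes the expected ranking regardless of the random expression draws —
shared family terms are identical between nested candidates, so the
superset always outscores the subset. The generator does not model
kinetic/mass-action titration, site accessibility or competition
non-linearities.

## TF enrichment

Promoter windows default to 1 kb upstream of the TSS (downstream 0),
protein-coding genes only, strand-aware. The null is the simplest
reproducible one: each peak keeps its width and is re-placed uniformly on
a chromosome chosen proportional to its length, with no gap or blacklist
exclusion (an exclusion hook would refine rather than change the design).
The 2×2 table is (gene-set promoters hit / not hit) × (real / random
peaks), "hit" meaning ≥ 1 bp overlap counted once per promoter; the
alternative reading (gene set vs all genes under real peaks) can be
assembled from `overlap_counts` directly. The test is one-sided in the
enrichment direction; the reported odds is the sample odds ratio
(a·d)/(b·c), infinite when b·c = 0. No multiple-TF correction is applied
by default; `benjamini_hochberg` is available. Enrichment-scatter
thresholds (minimum odds, minimum −log10 p) are mandatory arguments — no
default pretends to be a published cutoff.

## Problem sizes and numerical checks

The test and acceptance runs use: 2000-gene × 22-sample atlases (5–20
seeds), 60–200-gene toy chromosomes, 500-peak sets, 1000 random 1-kb
sequences × 5 miRNAs for scanner-oracle equivalence, all 2×2 tables with
N ≤ 60 (~3.3 × 10⁵ after transpose symmetry) for Fisher exactness at
1e-12, and 1000 simulated null tables for calibration. These sizes make
every statistical check decisive while the whole suite stays in the
single-digit minutes on one CPU. Poisson tails are validated against
closed-form partial sums (`math.fsum`) to 1e-12 for k ≤ 20 and remain
finite in log space far beyond float underflow.

## Known limitations

* Read-level processing (alignment, peak calling, FPKM quantification,
  differential expression) is upstream of this package and out of scope.
* The real discovery-scale numbers depend on consortium-scale atlases and
  merged annotations; the synthetic reconstructions validate the
  machinery, not those datasets.
* Gene-level TSSs are taken from the annotation as given; isoform-specific
  alternative TSSs are not modelled.
* The ceRNA score is a ranking heuristic, not a kinetic model; absolute
  score values have no physical unit.
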