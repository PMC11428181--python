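# stemlinc

A tested Python pipeline for discovering transcription-factor-dependent,
stem-cell-specific lincRNAs and characterizing their microRNA-sponge
behaviour. The package covers the computational chain that connects an
expression atlas, a TF ChIP-seq peak set and transcript sequences:

1. **Specificity scoring** — for each gene with cross-tissue FPKM vector
   *X*, the specificity of sample *i* is the cosine against the ideal
   one-hot profile, `SPM_i = x_i / ‖X‖₂` (so `Σ_i SPM_i² = 1`). After an
   abundance filter (max FPKM ≥ 1), k-means (k = 2) on the focal-sample SPM
   plus a detection rule (expressed in the focal sample and at most one
   other tissue) yields the focal-condition-specific gene set.
2. **Peak annotation** — ChIP peaks are categorized by summit position
   (promoter > exon > first intron > other intron > distal intergenic,
   promoter = TSS ± 1 kb by default) and associated with the most
   TSS-proximal gene *on each strand* within ±5 kb of the summit. Specific
   lincRNAs with an associated peak form the TF-bound ("lincS") set.
3. **MRE scanning** — transcripts are scanned for strict canonical miRNA
   seed sites (8mer-1a, 7mer-m8, 7mer-A1; Watson–Crick only). Site counts
   are tested with an upper-tail Poisson model, `p = P(X ≥ k)` with
   `X ~ Poisson(λL)`, where λ is the mean site density per kb of the
   background transcriptome and L the transcript length in kb; spacing
   regularity reports the modal inter-site distance and how many sites sit
   on that grid.
4. **ceRNA ranking** — each mRNA sharing at least one miRNA family with the
   sponge lncRNA gets a susceptibility score
   `Σ_f E(miR_f)·n_f(mRNA)·[n_f(lnc)·E(lnc) / Σ_t n_f(t)·E(t)]`
   (the sponge's share of each family's expression-weighted target pool),
   and candidates are ranked by decreasing score.
5. **TF enrichment** — a one-sided Fisher exact test compares how many
   gene-set promoters (1 kb upstream windows) are hit by a TF's real peaks
   versus length-preserving, uniformly re-placed random peaks.

Every stage is exercisable without any download: `stemlinc.synthetic_data`
generates atlases, annotations, peak sets, site-planted transcripts and
ceRNA systems with known ground truth.

## Worked example

```bash
python examples/03_mre_scan.py
```

```
miR-128-3p: 22 strict sites (8mer-1a 1, 7mer-m8 21, 7mer-1a 0); modal spacing 22 nt, 20 sites on that grid
miR-138-5p: 17 strict sites (8mer-1a 12, 7mer-m8 0, 7mer-1a 5); modal spacing 45 nt, 16 sites on that grid

background rate lambda = 0.107 sites/kb (300 random 1-kb transcripts)
P(X >= 22) with mu = lambda * 3.3 kb: p = 6.71e-32  (-log10 p = 31.2)
```

The scanner finds 22 strict miR-128-3p response elements on the synthetic
3.3 kb sponge transcript — 21 of the 7mer-m8 class, 20 of them spaced
exactly 22 nt apart — and 17 miR-138-5p elements (12 8mer-1a, 5 7mer-A1).
Against a neutral background rate of ~0.1 sites/kb, observing 22 sites in
3.3 kb has a Poisson tail probability of ~10⁻³², i.e. the transcript is
organised as a sponge for these families rather than matching them by
chance. The other examples (`examples/01…05`) walk through the atlas,
peak, ceRNA and TF-enrichment stages the same way, each printing the
numbers it computes and what they mean.

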