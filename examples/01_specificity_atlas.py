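"""Score a tissue atlas for ES-specific genes and recover the planted set.

Builds a synthetic FPKM atlas (2000 genes x 22 samples, 100 genes expressed
only in the ES-like focal sample at 10-fold over their off-state), then runs
abundance filtering, SPM scoring, k-means and the detection rule.
"""
from stemlinc import make_atlas, recover_truth, run_specificity

matrix, truth = make_atlas(
    n_genes=2000, n_tissues=22, n_specific=100, fold=10, noise_sd=0.3, seed=17
)
selected, table = run_specificity(matrix, min_fpkm=1.0, k=2, seed=17)
sensitivity, precision = recover_truth(selected, truth)

print(f"genes passing the FPKM >= 1 filter : {len(table)}")
print(f"genes selected as focal-specific   : {len(selected)}")
print(f"sensitivity vs planted truth       : {sensitivity:.3f}")
print(f"precision   vs planted truth       : {precision:.3f}")
print(
    "\nA sensitivity/precision near 1 means the SPM + k-means + detection-rule"
    "\nchain isolates exactly the genes planted as single-condition-specific."
)
print("\ntop of the per-gene table:")
print(table[["focal_spm", "cluster", "selected"]].sort_values(
    "focal_spm", ascending=False).head())
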