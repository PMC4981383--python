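"""Compositional normalization of an OTU count table.

Builds a tiny count table, filters it, and walks the two normalization
branches: TSS proportions followed by CLR/ILR log-ratio coordinates, and
cumulative sum scaling (CSS) of the raw counts.
"""

import numpy as np

from mixmc import CountTable, add_pseudocount, clr, css, ilr, prefilter, tss

table = CountTable(
    values=np.array([
        [120, 30, 0, 4, 846],
        [80, 0, 10, 2, 908],
        [3, 1, 0, 0, 2],      # shallow sample: dropped by the filter
        [200, 45, 5, 0, 750],
    ]),
    sample_ids=["gutA", "gutB", "shallow", "gutC"],
    feature_ids=[f"OTU_{j}" for j in range(1, 6)],
)

filtered = prefilter(table, min_sample_total=10, min_otu_prop=1e-4)
print(f"filtered table: {filtered.n_samples} samples x {filtered.n_features} OTUs")

# log-ratio branch: pseudocount -> proportions -> CLR / ILR
comp = tss(add_pseudocount(filtered))
y_clr = clr(comp)
y_ilr = ilr(comp)
print("CLR row sums (should all be ~0):", np.round(y_clr.values.sum(axis=1), 12))
print("ILR coordinates (p-1 =", y_ilr.n_features, "per sample):")
print(np.round(y_ilr.values, 3))

# CSS branch: scaling by the partial sum up to a data-driven quantile
z = css(filtered, percentile="auto", log_base=2)
print("CSS-normalized log2 counts, first sample:", np.round(z.values[0], 2))
print("Interpretation: CLR/ILR place samples in Euclidean (Aitchison) space;")
print("CSS rescales counts so sequencing depth differences cancel.")
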