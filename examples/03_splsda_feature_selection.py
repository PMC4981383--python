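"""Sparse PLS-DA: discriminating habitats and selecting marker OTUs.

Simulates data with known discriminative OTUs, tunes the number of
features per component by cross-validation, and checks the selection
against the planted ground truth.
"""

from mixmc import (
    SynthConfig,
    add_pseudocount,
    clr,
    cross_validate,
    evaluate_recovery,
    prefilter,
    simulate_counts,
    tss,
    tune_keepx,
)

table, meta, truth = simulate_counts(SynthConfig(seed=42))
filtered = prefilter(table)
X = clr(tss(add_pseudocount(filtered)))
labels = meta.labels_for(X.sample_ids)
subjects = meta.subjects_for(X.sample_ids)

tuned = tune_keepx(
    X, labels, keepX_grid=[5, 10, 15, 20, 30, 50],
    max_comp=3, folds=10, repeats=10, seed=42,
)
print(f"tuned model: {tuned.n_comp} components, keepX = {tuned.chosen_keepX}")

cv = cross_validate(
    X, labels, subjects=subjects, n_comp=tuned.n_comp,
    keepX=tuned.chosen_keepX, folds=10, repeats=10, seed=42, multilevel=True,
)
for h, (err, ber) in enumerate(zip(cv.overall_error, cv.balanced_error), 1):
    print(f"  component {h}: CV error {err:.3f} (balanced {ber:.3f})")

selected = {
    h + 1: tuned.final_model.selected_features(h)
    for h in range(tuned.n_comp)
}
res = evaluate_recovery(selected, truth)
print(f"selected {res['n_selected']} OTUs; "
      f"precision {res['precision']:.2f}, recall {res['recall']:.2f} "
      "against the planted discriminative sets")
print("High precision/recall means the sparse components point at the OTUs")
print("that actually carry the habitat signal, not at compositional noise.")
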