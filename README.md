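# mixmc

Multivariate analysis of microbiome OTU count tables: compositional
normalization, repeated-measures variance decomposition, and multiclass
sparse discriminant analysis with cross-validated marker selection.

## The problem

16S rRNA surveys deliver sparse, overdispersed OTU count tables whose
rows only carry *relative* information: sequencing depth varies per
sample, so counts must be normalized, and the resulting proportions live
on a simplex where standard Euclidean statistics mislead. On top of
that, multi-habitat designs (the same subjects sampled in several body
sites) bury the habitat signal under large between-subject variability.
`mixmc` is for microbiome analysts who want, beyond an ordination plot,
a ranked list of the OTUs that actually discriminate their sample
groups.

## The methods

**Compositional transforms.** Total sum scaling maps counts to
proportions x = (x₁,…,x_p) on the simplex. The centered log ratio

y_j = log( x_j / g(x) ),  g(x) = (∏ᵢ xᵢ)^{1/p}

maps the simplex to the zero-sum hyperplane of ℝᵖ; the isometric log
ratio (pivot coordinates)

z_i = √(i/(i+1)) · log( g(x₁…x_i) / x_{i+1} ),  i = 1…p−1

gives p−1 orthonormal coordinates preserving Aitchison geometry.
Cumulative sum scaling (CSS) instead divides each sample's counts by the
partial sum of its counts up to a data-driven quantile. Prefiltering
drops samples with fewer than 10 total counts and OTUs below 0.01% of
the grand total.

**Multilevel decomposition.** For repeated measures, X splits exactly
into a between-subject part (subject means) and a within-subject part
(deviations); the within part, free of subject effects, feeds the
downstream analyses.

**Sparse PLS-DA.** A dummy outcome matrix Y (one indicator column per
class) and the feature matrix X are linked by latent components
t_h = X_h u_h that maximize cov(X u, Y v) sequentially; a componentwise
Lasso (soft-thresholding of u_h) leaves exactly keepX[h] OTUs with
nonzero weight. keepX and the number of components are tuned by repeated
stratified cross-validation; with a repeated-measures design, folds are
drawn at the subject level and the within-decomposition is recomputed
inside each training split. Selected OTUs are assigned to the class with
the highest median normalized abundance, exported as contribution tables
and GraPhlAn cladogram annotations.

## Worked example

```python
from mixmc import (SynthConfig, simulate_counts, prefilter, add_pseudocount,
                   tss, clr, tune_keepx, evaluate_recovery)

table, meta, truth = simulate_counts(SynthConfig(seed=42))   # 150 samples x 300 OTUs
X = clr(tss(add_pseudocount(prefilter(table))))
labels = meta.labels_for(X.sample_ids)
tuned = tune_keepx(X, labels, keepX_grid=[5, 10, 15, 20, 30, 50],
                   max_comp=3, folds=10, repeats=10, seed=42)
print(tuned.n_comp, tuned.chosen_keepX)
sel = {h + 1: tuned.final_model.selected_features(h) for h in range(tuned.n_comp)}
print(evaluate_recovery(sel, truth))
```

prints

```
2 [15, 30]
{'precision': 0.9, 'recall': 0.9, 'per_class_recall': {'site_1': 0.9,
 'site_2': 1.0, 'site_3': 0.8}, 'n_selected': 30, 'n_true': 30}
```

Two latent components suffice for three habitats; the tuned model keeps
15 + 30 OTU weights, and 27 of the 30 selected OTUs are exactly the ones
the simulation planted as discriminative (precision 0.9) while
recovering 27 of the 30 planted ones (recall 0.9).

The `examples/` directory holds one narrative script per capability
(transforms, multilevel + ordination, sparse PLS-DA tuning,
interpretation exports), and the `mixmc` command line mirrors the same
pipeline (`mixmc simulate | filter | transform | pca | pcoa | tune |
splsda | run | report`).

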