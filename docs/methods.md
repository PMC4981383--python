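# Methods

This note records the statistical models implemented in `mixmc`, the
choices made where conventions diverge, and what the synthetic data can
and cannot certify.

## Prefiltering and zero handling

Samples with fewer than `min_sample_total` (default 10) total counts are
removed first; OTUs are then kept iff their aggregate count is at least
`min_otu_prop` (default 10⁻⁴, i.e. 0.01%) of the post-filter grand
total. The boundary is inclusive: exactly 0.01% survives, since removal
targets proportions *below* the threshold. Filtering never alters
surviving counts, and the pair of filters is idempotent.

Log ratios need strictly positive entries. The default is a pseudocount
of 1 added to the raw counts before total sum scaling — the simplest
offset that preserves count semantics. Multiplicative zero replacement
(replace zero proportions by a small δ, shrink the positive parts so
rows still sum to one) is provided as an alternative
(`preprocess.multiplicative_replacement`); with the heavy zero fraction
of OTU tables the two differ mostly in how hard they pull rare OTUs
toward the geometric mean. CSS operates on raw counts and must not be
pseudocounted; the pipeline enforces this.

## Normalizations

* **TSS** divides each sample by its library size; rows land on the
  simplex.
* **CLR** is log(x_j / geometric mean); rows sum to zero, one coordinate
  per OTU — required by the feature-selection step, which must weight
  individual OTUs.
* **ILR** uses pivot coordinates: coordinate i contrasts the geometric
  mean of the first i parts against part i+1, scaled √(i/(i+1)). The
  (p−1)×p contrast matrix V has orthonormal rows summing to zero, so
  ILR = CLR·Vᵀ and Euclidean distance on ILR coordinates is the
  Aitchison distance. Any orthonormal basis gives the same geometry;
  pivot coordinates are fixed for determinism. PCA runs on ILR because
  CLR's zero-sum constraint makes its covariance singular.
* **CSS** rescales sample j by s_j/1000, where s_j is the sum of sample
  j's counts not exceeding its own l-quantile (computed over positive
  counts). The level l is chosen data-adaptively: scanning upward from
  the median, the first level at which the median absolute deviation of
  the per-sample quantiles around their across-sample mean jumps by more
  than 10% relative; 0.5 if the scan never triggers. The normalization
  constant 1000 and the subsequent log₂(x+1) follow the convention of
  the method's reference implementation; the log base is configurable
  (`2`, `e`, `none`) because published analyses are not explicit about
  it. Scaling precedes the log.

## Multilevel decomposition

With subject ids s(i), the between part is B_i = mean{X_r : s(r)=s(i)}
and the within part W = X − B. The identity X = W + B is exact and each
subject's within rows average to zero; for balanced designs the
column-centered total sum of squares splits into SS(W) + SS(B). The
grand mean is *not* added back to W — downstream methods center columns
anyway, and keeping W mean-free makes its rows interpretable as pure
within-subject contrasts. Unbalanced designs use plain per-subject
means (unweighted). Singleton subjects are an error by default; with
`allow_singletons` their within row is zero, which silently removes
them from the discriminant signal — acceptable inside cross-validation
folds, undesirable in a final fit. The decomposition ignores any
ordering of the repeats and is therefore not a time-course model.

## Ordination

PCA centers columns (no unit-variance scaling by default: log-ratio
coordinates share a scale) and reports scores, loadings and
per-component explained variance. PCoA double-centers −½D² and
eigendecomposes; coordinates are eigenvectors scaled by the square root
of positive eigenvalues. Non-Euclidean dissimilarities (Bray-Curtis)
produce negative eigenvalues; these are dropped, their count reported,
and explained fractions are taken over the positive spectrum only (no
Cailliez/Lingoes correction). On Euclidean distances PCoA reproduces
PCA scores up to sign — a standing test.

## Sparse PLS-DA

The outcome is a centered dummy matrix Y (n×K). Per component the
algorithm seeks the dominant pair of the cross-covariance M = X_hᵀY_h:
starting from the leading right singular vector of M, it alternates

1. u ← soft-threshold(M v) with the (keepX+1)-th largest |entry| as
   threshold — survivors shrink toward zero, signs kept, exactly keepX
   nonzeros — then normalize;
2. v ← Mᵀu / ‖Mᵀu‖,

until the change in u falls below 10⁻⁶. Step 2 keeps uᵀMv non-negative,
making the alternation a monotone ascent; the deterministic sign
convention (largest-|u| entry positive) is applied jointly to (u, v)
only after convergence, because flipping the vectors independently
inside the loop destroys the ascent property. The alternation can end
in a two-cycle between equally covariant supports — detected and
accepted — and on noise-dominated residuals (components past the
class-space rank K−1) the two leading singular values of M nearly
coincide, so the iteration crawls through a saddle; the cap is 5000
iterations, far above the worst case observed (~700), and genuine
non-convergence raises.

Scores are t = X_h u; both blocks are deflated by their regression on t
(X_{h+1} = X_h − t pᵀ, Y_{h+1} = Y_h − t cᵀ). With keepX = p the
thresholding vanishes and the model coincides with dense PLS-2 — tested
to 10⁻⁸ against an independent NIPALS implementation and, for the
sparse case, against the mixOmics R implementation on a fixture.

**Prediction.** Default rule `max`: argmax over classes of the
predicted dummy outcome X_c W*(PᵀW*)⁻¹Cᵀ + ȳ. `centroid` (nearest class
centroid in score space) and a naive `mahalanobis` variant are
provided; `max` follows the reference ecosystem's default but, like any
least-squares dummy rule, can mask a class sitting between two others —
the centroid rule is preferable when that geometry is suspected.

**Cross-validation.** Stratified k-fold (default 10), repeated; mean
and standard deviation of the overall error across repeats, plus the
balanced error rate (mean of per-class errors) and per-class errors per
component count. Folds failing to keep every class in training are
redrawn (up to 10 attempts). With a repeated-measures design, folds are
drawn at the *subject* level (stratified grouped folds) and the within
decomposition is recomputed on each training split; test subjects are
decomposed with their own means. This prevents subject means leaking
across the split; `legacy_cv` reproduces the simpler row-level folding
of a precomputed within matrix.

**Tuning.** Sequential per component: with earlier components frozen,
every grid value is evaluated on the same folds and the minimizer of
the mean error wins, ties to the smallest keepX (parsimony). Components
stop being added when the error no longer improves on the previous
component by more than one standard deviation. The final model is refit
on all data. The default grid {5,10,…,50} ∪ {60,80,…,200}∩[1,p] spans
the selection sizes typical for 16S biomarker panels. Note that when
classes are easily separated the error surface is flat at its floor and
the parsimony rule picks the smallest panel consistent with minimal
error — selections are then precise but may not exhaust a larger true
marker set; when the error keeps creeping down with panel size the rule
instead returns generous panels (high recall, lower precision). Both
regimes are visible on simulated data depending on the seed.

## Interpretation outputs

Each selected OTU's median normalized abundance is computed per class on
the normalization used for the fit, *before* the multilevel step (within
values lose abundance meaning); the class attaining the maximum median
is the OTU's assigned habitat. Exact ties are flagged and all tied
classes recorded (plots are expected to grey them out) — ties are
common under CSS, whose discreteness leaves many equal medians. Rows
are ordered by |loading| within component. The GraPhlAn export writes
`clade<TAB>attribute<TAB>value` annotation lines: marker size scales
affinely (4–20) with the median abundance in the assigned class, marker
color encodes the loading sign (yellow positive, black negative, grey
ties), background color keys the assigned class; a companion tree file
lists the lineage paths. Confidence ellipses per class come from the
2-D mean and covariance of the scores with radius √(χ²₂(level)); they
are Gaussian large-sample contours, checked by Monte-Carlo coverage.

## Synthetic data

The generator emulates a multi-habitat 16S survey with a
Dirichlet-multinomial: a log-normal baseline rank-abundance profile
(σ = 1.5) rescaled to total concentration c = 50 (small c ⇒ strong
overdispersion, ~65% zeros at the default sizes); per-subject log-normal
random effects on the concentrations (σ = 1.0), shared across a
subject's samples, creating the between-subject variance the multilevel
step removes; a disjoint set of 10 planted OTUs per habitat whose
concentrations are multiplied by the effect size (8 by default); library
sizes log-normal around 10⁴ reads. Default design: 50 subjects × 3
habitats × 300 OTUs. Everything is reproducible from one seed, and rows
sum exactly to the drawn library sizes.

What the simulation does **not** reproduce: phylogenetic correlation
between OTUs, batch/run-center effects, unbalanced or partially repeated
designs (available by configuration but not defaulted), taxon-specific
amplification bias, and zero inflation beyond what the
Dirichlet-multinomial induces. Tests passing on this generator certify
the algebra and the selection machinery under a standard compositional
null, not performance on any particular real survey.

## Problem sizes and numerical conventions

Bulk identity checks use 1,000 random compositions and 20 random
repeated-measures designs; the permutation-null check uses a 100×50
noise matrix with 20 label permutations of 10-fold CV; recovery runs
the full default simulation (150 samples × 300 OTUs) with a 6-point
grid, 10-fold × 10-repeat tuning. Tolerances: 10⁻¹⁰ for algebraic
identities (CLR row sums, multilevel reconstruction), 10⁻⁸ for
spectral agreements (NIPALS equivalence, PCoA/PCA duality), ±0.05 for
the chance-level error, ±0.02 for ellipse coverage. Ties in
soft-thresholding (measure zero for continuous data) are retained at
negligible weight so the keepX count stays exact; PCoA eigenvalues
within machine precision of zero count as neither positive nor
negative.
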