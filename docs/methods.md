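# Methods

## Model and procedure

The selector treats feature selection as a two-signal trade-off:
per-feature *relevance* (how well a feature separates the classes) and
*redundancy* (how much of that signal is already carried by other
features). Relevance is estimated by ReliefF on a kernel-PLS latent
reconstruction of the data; redundancy by absolute Pearson correlation;
the two are combined in a greedy forward pass maximizing
R_j = α·w_j − (1 − α)·r_j.

Assumptions worth stating explicitly:

- **Numeric, complete data.** Features are real-valued measurements on a
  common sample set; rows with missing entries are rejected at load time
  rather than imputed, because the weighting and redundancy statistics
  have no missing-data model and silent imputation would change results
  invisibly.
- **Classification labels.** The label is categorical with at least two
  classes, each with at least two members (ReliefF and the Fisher score
  need within-class neighbours/variances). Stratified cross-validation
  additionally needs every class at least as large as the fold count.
- **Pearson redundancy is linear.** Two features related through a
  strongly nonlinear map can evade the redundancy term; the kernel stage
  mitigates but does not remove this.

### Kernel-PLS stage

The Gaussian Gram matrix K[i,j] = exp(−‖x_i − x_j‖²/s) is
double-centered and score vectors are extracted by the standard
power-type iteration (t ∝ K u, c = Yᵀ t, u ∝ Y c), deflating K and the
centered one-hot indicator Y by (I − t tᵀ) after each component. The
fixed point of the first component is the dominant eigenvector of
K Y Yᵀ, which the test suite verifies against a dense eigensolver.
Scores are orthonormal by construction.

ReliefF then runs on the rank-p reconstruction T Tᵀ X_c + column means
rather than on the p score columns: the reconstruction lives in the
original m feature coordinates, so each weight still names a real
feature, while directions of X orthogonal to the label-driven score
space are damped.

### Greedy criterion and the redundancy reference set

At each step the candidate's redundancy r_j is the mean (configurable:
min/max) of |Pearson r| against a reference set. Two reference sets are
implemented:

- `redundancy_target="pool"` (default): the other *non-selected*
  candidates — the set the greedy loop's literal update iterates over,
  and the mode in which the benchmark's three informative features are
  all recovered at α = 0.3. Intuitively it penalizes features that are correlated with many
  still-available alternatives *relative to their peers*; since the
  penalty is nearly uniform when redundancy is diffuse, relevance
  dominates and correlated informative features can all be kept.
- `redundancy_target="selected"`: the already-selected subset, the
  convention of the wider minimum-redundancy (mRMR-style) literature.
  This actively de-duplicates: an exact copy of a selected feature has
  r = 1 and, for α ≤ 0.5, provably loses to any zero-redundancy
  candidate at the step after its twin is chosen. The cost is that
  *informative* features that are mutually correlated through the class
  signal itself (on the synthetic benchmark, pairwise |r| ≈ 0.94) are
  also suppressed at small α, so pure-noise features can outrank them.

Which behaviour is wanted depends on whether between-feature correlation
is regarded as waste (use `"selected"`) or as shared evidence (use
`"pool"`). The default recovers the benchmark's informative features;
the duplicated-feature guarantees in the test suite use `"selected"`.

Absolute correlation is used in both modes: redundancy is magnitude of
association, and a signed score would reward anti-correlated copies of
already-selected features.

## Parameters

| Parameter | Default | Units / range | Rationale |
| --- | --- | --- | --- |
| `alpha` | 0.3 | dimensionless, [0, 1] | Benchmark optimum of the accuracy-vs-α sweep; α < 0.5 is typical across datasets. |
| `n_features_to_select` (k) | 3 | count | The benchmark's informative dimensionality; set per application. |
| `kernel_width` (s) | `"median"` | squared data units | Median of all pairwise squared distances: deterministic, scale-adaptive, no tuning loop. A fixed positive float may be supplied instead. |
| `n_components` (p) | 20 | count, clipped to n−1 and rank(K) | Enough latent directions that the reconstruction preserves per-feature identity. A very low p (≈ the class count) makes the reconstruction nearly class-rank: noise columns then alias onto the score directions and acquire spurious ReliefF weight (observed directly on the benchmark at p = 5, where the best noise weight matched the informative weights). p = 20 leaves a wide margin there while staying cheap; the cost of larger p is only O(p·n²). |
| `relieff_k_neighbors` | 10 | count, clipped to min class size − 1 | The customary ReliefF neighbourhood size; results on the benchmark are insensitive between 5 and 20. |
| `redundancy_aggregate` | `"mean"` | — | Stable scalarization of per-pair correlations; `min`/`max` exposed for sensitivity checks. |
| `normalize_weights` | `True` | — | Min-max rescales ReliefF weights onto [0, 1], the same scale as |r|, so α has a consistent meaning across datasets. |
| `n_folds` / `n_repeats` | 10 / 10 | count | Repeated stratified 10-fold CV; metrics are fold-averaged (not pooled), matching how such tables are usually reported. |
| SVM | linear, C = 1 | — | Pluggable `fit`/`predict` contract; the default matches the benchmark's base classifier. Multiclass handling is the classifier's own (one-vs-one for `SVC`). |

## Synthetic benchmark

`synthetic.generate` draws three balanced classes (100 samples each)
whose informative features share one Gaussian per class — N(5, 1),
N(10, 1), N(15, 1) — plus label-independent noise features N(0, 0.01)
(variance convention; the noise is class-free either way, so rankings do
not depend on the reading). Because all informative features carry the
same class means, they are strongly mutually correlated (|r| ≈ 0.94),
which is exactly what makes the benchmark a sharp test of how a
redundancy term treats correlated-but-informative features.

What the generator does *not* emulate — and hence what passing tests do
not demonstrate about real data: correlated noise structure, heavy tails
and outliers, class imbalance, nonlinear class boundaries, features
informative only in interaction, and measurement batch effects. The
benchmark's classes are far apart (5 within-class SDs), so cross-validated
accuracies saturate near 1.0 once any informative feature is kept;
discrimination between selection methods rests on *which* features they
pick, not on accuracy differences.

## Numerical choices

- Determinism: the score iteration initializes u from the first column
  of the current (deflated) indicator rather than randomly; ReliefF uses
  all samples; every RNG consumer takes an explicit seed.
- Component count is clipped to min(p, n − 1, numerical rank of K) with
  a warning; a component whose iteration exhausts `max_iter` (default
  500, tol 1e−8 on the change in t) is accepted with a warning.
- Zero-variance vectors: Pearson r is defined as 0 (no evidence of
  association); ReliefF diffs on a constant feature are 0; a Fisher
  score with zero within-class variance but distinct means is assigned
  the largest finite score instead of +inf.
- Ties: neighbour ties break by ascending sample index; criterion ties
  break by higher raw weight, then lower column index. Selection is
  therefore bit-reproducible across platforms.
- Degenerate metrics: Cohen's κ with pe = 1 is defined as 0 with a
  warning; per-class F1 with an empty precision or recall denominator
  counts as 0 in the macro average.
- Min-max normalization of an all-equal weight vector returns all zeros.
- The median kernel width errors out when all pairwise distances are
  zero (identical samples) instead of returning a degenerate kernel.

## Evaluation protocol

`cross_validate` supports two selection modes. `select_once` fixes the
subset on the full data and cross-validates the classifier only — this
is how benchmark-style tables are produced, and it is what
`scripts/acceptance.py` recomputes. `within_fold` (the default) re-runs
the selector callback inside every training split so the held-out fold
never influences selection; an instrumented-selector test asserts this.
`select_once` numbers are optimistic on small datasets and should not be
quoted as generalization estimates.

Problem sizes used by the shipped tests and acceptance script: the
300 × 103 benchmark for the headline comparisons; 300 × (103–503) for
the noise-robustness curve (noise grid 100/300/500, subset sizes 1–15,
single 10-fold repeat); 100 seeded replicates for the
informative-vs-noise ranking rate; toys of 6–25 samples for the oracle
equivalences. These sizes keep every statistic stable across seeds while
the whole suite runs in well under a minute.

## Known limitations

- The greedy pass is O(k·m²) in correlations (precomputed once, O(m²·n));
  for m in the tens of thousands the correlation matrix dominates memory
  and a blocked or on-demand computation would be needed.
- Kernel-PLS costs O(p·n²) after an O(n²·m) Gram build; n in the tens of
  thousands calls for Nyström-type approximation, out of scope here.
- The latent reconstruction interpretation (weights on reconstructed
  features rather than on score columns) is the only dimensionally
  consistent reading of the procedure this package implements; the raw
  score matrix is exposed (`KernelPLS.x_scores_`) for inspection.
- No missing data, no feature scaling beyond ReliefF's internal range
  normalization, no search strategies beyond greedy forward selection.
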