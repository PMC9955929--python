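# kplsmwmr

Supervised feature selection for high-dimensional biomedical
classification matrices (gene-expression panels, spectral features,
clinical measurement tables): pick a small, non-redundant subset of
features that preserves class discrimination, so a downstream classifier
trains faster and generalizes better.

## Method

Given a data matrix **X** ∈ ℝ<sup>n×m</sup> (n samples, m features) and a
class label per sample, the selector works in three stages:

1. **Kernel-PLS latent mapping.** A Gaussian Gram matrix
   K(x, y) = exp(−‖x − y‖² / s) is built and double-centered; score
   vectors t₁…t_p maximizing covariance with the centered one-hot label
   indicator **Y** are extracted iteratively (t ∝ K u, c = Yᵀt, u ∝ Y c,
   with deflation of both K and Y per component). The rank-p
   reconstruction T Tᵀ X_c + means maps the latent structure back to the
   original m features, suppressing directions of X unrelated to the
   class structure while keeping the feature coordinates.
2. **ReliefF weighting.** Each feature f gets a weight
   W(f) ∈ [−1, 1] contrasting its range-normalized differences to the
   k nearest same-class neighbours against its prior-weighted differences
   to the k nearest neighbours of every other class, computed on the
   latent reconstruction over all n samples (no subsampling).
3. **Greedy max-weight/min-redundancy selection.** Features are added one
   at a time, maximizing

   R_j = α·w_j − (1 − α)·r_j

   where w_j is the min-max-normalized weight and r_j is the mean
   absolute Pearson correlation of the candidate with a redundancy
   reference set (by default the remaining candidate pool; optionally the
   already-selected subset). The weight factor α ∈ [0, 1] tunes the
   trade-off: α = 1 is pure relevance ranking, α = 0 pure redundancy
   minimization after the first pick.

ReliefF-only and Fisher-score rankings are included as baselines, and a
repeated stratified 10-fold cross-validation harness (linear SVM, C = 1;
accuracy, Cohen's κ, macro-F1) evaluates any selected subset. Everything
is deterministic given explicit seeds.

The three selectors are scikit-learn estimators
(`KPLSMWMRSelector`, `ReliefFSelector`, `FisherScoreSelector` — all
`SelectorMixin` transformers), so they drop into sklearn pipelines and
model selection.

## Worked example

Generate the built-in synthetic benchmark — three balanced classes of 100
samples whose 3 informative features are drawn from N(5, 1), N(10, 1) and
N(15, 1) per class, plus 100 label-independent noise features
N(0, 0.01) — then select and evaluate:

```sh
$ kpls-mwmr synth --seed 42 -o synth.csv
wrote 300x103 matrix to synth.csv

$ kpls-mwmr select --data synth.csv --alpha 0.3 --k 3 -o report.json -v
step 1: chose f3 (w=1.0000, r=0.0000, R=1.0000, pool=103)
step 2: chose f2 (w=0.9952, r=0.0530, R=0.2615, pool=102)
step 3: chose f1 (w=0.9608, r=0.0430, R=0.2582, pool=101)
selected 3 features -> report.json

$ kpls-mwmr evaluate --data synth.csv --report report.json --seed 7
{ ... "features": ["f3", "f2", "f1"],
  "metrics": {"accuracy": {"mean": 1.0, "sd": 0.0},
              "kappa": {"mean": 1.0, "sd": 0.0},
              "macro_f1": {"mean": 1.0, "sd": 0.0}} }
```

Reading the trace: at each step `w` is the candidate's normalized ReliefF
weight, `r` its aggregated |Pearson| redundancy and `R = 0.3·w − 0.7·r`
the criterion value of the winner. The selector recovers exactly the
three informative features out of 103; a linear SVM on them classifies
the benchmark perfectly under 10×10-fold cross-validation. The same
operations are available from Python:

```python
from kplsmwmr import KPLSMWMRSelector, SynthConfig, generate

X, y = generate(SynthConfig(seed=42))
sel = KPLSMWMRSelector(alpha=0.3, n_features_to_select=3).fit(X.values, y.labels)
print(sel.selected_feature_names())   # ['f3', 'f2', 'f1']
```

`kpls-mwmr sweep-alpha` scans the weight factor over a grid and emits a
CSV of cross-validated accuracies per α.

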