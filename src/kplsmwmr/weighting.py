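"""Per-feature relevance weights: ReliefF and the Fisher-score baseline.

ReliefF scores a feature by contrasting its value differences between
each sample and its k nearest same-class neighbours ("hits") against the
differences to its k nearest neighbours in every other class ("misses"),
the latter weighted by class priors. Features whose values separate
classes locally gain weight; features that vary as much within as between
classes drift to zero. All n samples are used deterministically (no
subsampling), distances are Manhattan on range-normalized features, and
neighbour ties break by ascending sample index, so the weights are a pure
function of the data.

The Fisher score is the classical between-class over within-class
variance ratio, kept here as the standard filter baseline.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

from .io import ConfigurationError, DataFormatError, FeatureMatrix, LabelVector

__all__ = [
    "WeightVector",
    "relieff_weights",
    "fisher_weights",
    "minmax_normalize",
]


@dataclass
class WeightVector:
    """Per-feature weights plus their min-max normalized copy."""

    weights: np.ndarray
    method: str
    normalized: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.ndim != 1:
            raise ConfigurationError("weights must be a 1-d vector")
        if self.normalized is None:
            self.normalized = minmax_normalize(self.weights)

    def __len__(self) -> int:
        return len(self.weights)

    def ranking(self) -> np.ndarray:
        """Feature indices in descending-weight order (ties: lower index)."""
        return np.lexsort((np.arange(len(self.weights)), -self.weights))


def minmax_normalize(weights: np.ndarray) -> np.ndarray:
    """Rescale to [0, 1] via (w - min)/(max - min); all-equal input -> zeros."""
    w = np.asarray(weights, dtype=float)
    lo, hi = w.min(), w.max()
    if hi == lo:
        return np.zeros_like(w)
    return (w - lo) / (hi - lo)


def _labels_of(y) -> LabelVector:
    return y if isinstance(y, LabelVector) else LabelVector(np.asarray(y))


def _values_of(X) -> np.ndarray:
    if isinstance(X, FeatureMatrix):
        return X.values
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ConfigurationError("expected a 2-d sample-by-feature matrix")
    return X


def relieff_weights(F, y, k_neighbors: int = 10) -> WeightVector:
    """ReliefF weights over all n samples (deterministic, no subsampling).

    For each sample x the weight of feature f is decreased by the mean
    range-normalized difference to the k nearest hits and increased by the
    prior-weighted mean difference to the k nearest misses of each other
    class:

        W[f] += sum_c!=cls(x) P(c)/(1-P(cls(x))) * sum_k diff(f)/ (n k)
                - sum_k_hits diff(f) / (n k)

    diff(f, a, b) = |a_f - b_f| / (max_f - min_f); constant features give
    diff 0 by convention. ``k_neighbors`` is clipped to (min class size - 1)
    with a warning; a singleton class is an error. Weights lie in [-1, 1].
    """
    X = _values_of(F)
    lv = _labels_of(y)
    n, m = X.shape
    if len(lv) != n:
        raise ConfigurationError(f"{len(lv)} labels for {n} samples")
    if k_neighbors < 1:
        raise ConfigurationError("k_neighbors must be >= 1")

    class_idx = lv.class_indices()
    counts = np.array([(class_idx == c).sum() for c in range(lv.n_classes)])
    smallest = counts.min()
    if smallest < 2:
        bad = lv.classes[int(np.argmin(counts))]
        raise DataFormatError(
            f"class {bad!r} has a single member; ReliefF needs >= 2 per class"
        )
    k = k_neighbors
    if k > smallest - 1:
        k = smallest - 1
        warnings.warn(
            f"k_neighbors={k_neighbors} exceeds smallest class size - 1; "
            f"clipped to {k}",
            stacklevel=2,
        )

    ranges = X.max(axis=0) - X.min(axis=0)
    safe = np.where(ranges == 0.0, 1.0, ranges)  # constant feature -> diff 0 anyway
    Xs = X / safe
    D = cdist(Xs, Xs, "cityblock")
    np.fill_diagonal(D, np.inf)

    priors = counts / n
    members = [np.where(class_idx == c)[0] for c in range(lv.n_classes)]
    W = np.zeros(m)
    for i in range(n):
        ci = class_idx[i]
        for c in range(lv.n_classes):
            idx = members[c]
            if c == ci:
                idx = idx[idx != i]
            # k nearest, ties by ascending sample index
            order = idx[np.lexsort((idx, D[i, idx]))][:k]
            diffs = np.abs(Xs[order] - Xs[i]).sum(axis=0)
            if c == ci:
                W -= diffs
            else:
                W += (priors[c] / (1.0 - priors[ci])) * diffs
    W /= n * k
    return WeightVector(W, method="relieff")


def fisher_weights(X, y) -> WeightVector:
    """Fisher scores: sum_c n_c (mu_cf - mu_f)^2 / sum_c n_c var_cf.

    Non-negative; a feature with zero within-class variance everywhere but
    distinct class means would be +inf and is assigned the largest finite
    score instead (top of the ranking without poisoning normalization).
    """
    Xa = _values_of(X)
    lv = _labels_of(y)
    n, m = Xa.shape
    if len(lv) != n:
        raise ConfigurationError(f"{len(lv)} labels for {n} samples")
    class_idx = lv.class_indices()
    counts = np.array([(class_idx == c).sum() for c in range(lv.n_classes)])
    if counts.min() < 2:
        bad = lv.classes[int(np.argmin(counts))]
        raise DataFormatError(
            f"class {bad!r} has a single member; Fisher score needs >= 2 per class"
        )
    mu = Xa.mean(axis=0)
    num = np.zeros(m)
    den = np.zeros(m)
    for c in range(lv.n_classes):
        block = Xa[class_idx == c]
        nc = len(block)
        num += nc * (block.mean(axis=0) - mu) ** 2
        den += nc * block.var(axis=0)  # population variance within class
    scores = np.zeros(m)
    ok = den > 0.0
    scores[ok] = num[ok] / den[ok]
    degenerate = (~ok) & (num > 0.0)
    if degenerate.any():
        finite_max = scores[ok].max() if ok.any() else 1.0
        scores[degenerate] = finite_max
    return WeightVector(scores, method="fisher")
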