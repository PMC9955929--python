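"""scikit-learn compatible selector estimators.

:class:`KPLSMWMRSelector` is the full pipeline (kernel-PLS latent
reconstruction -> ReliefF weighting -> greedy max-weight/min-redundancy
selection) behind the standard ``SelectorMixin`` surface, so it composes
with ``sklearn.pipeline.Pipeline`` and model selection.
:class:`ReliefFSelector` and :class:`FisherScoreSelector` are the plain
top-k filter baselines on the raw features.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.feature_selection import SelectorMixin
from sklearn.utils.validation import check_is_fitted, validate_data

from .io import FeatureMatrix, LabelVector
from .kpls import KernelConfig, KernelPLS
from .selection import MWMRConfig, mwmr_select
from .weighting import WeightVector, fisher_weights, relieff_weights

__all__ = ["KPLSMWMRSelector", "ReliefFSelector", "FisherScoreSelector"]


class _TopKSelectorBase(SelectorMixin, BaseEstimator):
    """Shared plumbing: validate inputs, build domain containers, expose
    ``support_`` from a fitted weight vector."""

    def _prepare(self, X, y):
        X = validate_data(self, X, dtype=np.float64, ensure_min_samples=2)
        y = np.asarray(y)
        if y.ndim != 1 or len(y) != X.shape[0]:
            raise ValueError(f"y must be 1-d with {X.shape[0]} entries")
        names = getattr(self, "feature_names_in_", None)
        if names is None:
            names = [f"x{j}" for j in range(X.shape[1])]
        fm = FeatureMatrix(X, list(names), [str(i) for i in range(X.shape[0])])
        lv = LabelVector(y)
        return fm, lv

    def _check_k(self, k: int, m: int) -> int:
        if not 1 <= k <= m:
            raise ValueError(f"n_features_to_select={k} not in [1, {m}]")
        return int(k)

    def _get_support_mask(self):
        check_is_fitted(self, "support_")
        return self.support_

    def selected_feature_names(self) -> list[str]:
        """Selected feature names in selection (or ranking) order."""
        check_is_fitted(self, "selected_names_")
        return list(self.selected_names_)


class KPLSMWMRSelector(_TopKSelectorBase):
    """Greedy kernel-PLS max-weight/min-redundancy feature selector.

    Parameters
    ----------
    n_features_to_select : int, default 3
        Size k of the returned subset.
    alpha : float in [0, 1], default 0.3
        Weight-vs-redundancy trade-off; 1 = pure weight ranking.
    kernel_width : float or "median", default "median"
        Gaussian kernel scale s; "median" uses the median pairwise
        squared distance.
    n_components : int, default 20
        Latent components p (clipped to n - 1 and the Gram rank).
    relieff_k_neighbors : int, default 10
        Hits/misses per class in the ReliefF weighting.
    redundancy_aggregate : {"mean", "max", "min"}, default "mean"
        How |Pearson r| values aggregate into one redundancy per candidate.
    redundancy_target : {"pool", "selected"}, default "pool"
        Redundancy measured against the remaining candidate pool (keeps
        correlated informative features) or the already-selected set
        (minimum-redundancy literature convention; de-duplicates).
    normalize_weights : bool, default True
        Min-max rescale ReliefF weights to [0, 1] before the criterion.

    Attributes
    ----------
    weights_ : ndarray of shape (m,)
        ReliefF weights computed on the latent reconstruction.
    ranking_ : ndarray of shape (k,)
        Column indices in selection order.
    support_ : boolean mask of shape (m,)
    report_, trace_ : the full selection report and per-step trace.
    """

    def __init__(
        self,
        n_features_to_select: int = 3,
        alpha: float = 0.3,
        kernel_width="median",
        n_components: int = 20,
        tol: float = 1e-8,
        max_iter: int = 500,
        relieff_k_neighbors: int = 10,
        redundancy_aggregate: str = "mean",
        redundancy_target: str = "pool",
        normalize_weights: bool = True,
    ):
        self.n_features_to_select = n_features_to_select
        self.alpha = alpha
        self.kernel_width = kernel_width
        self.n_components = n_components
        self.tol = tol
        self.max_iter = max_iter
        self.relieff_k_neighbors = relieff_k_neighbors
        self.redundancy_aggregate = redundancy_aggregate
        self.redundancy_target = redundancy_target
        self.normalize_weights = normalize_weights

    def fit(self, X, y):
        fm, lv = self._prepare(X, y)
        k = self._check_k(self.n_features_to_select, fm.n_features)
        kernel = KernelConfig(
            width_s=self.kernel_width,
            n_components_p=self.n_components,
            tol=self.tol,
            max_iter=self.max_iter,
        )
        mwmr = MWMRConfig(
            alpha=self.alpha,
            k=k,
            redundancy_aggregate=self.redundancy_aggregate,
            redundancy_target=self.redundancy_target,
            normalize_weights=self.normalize_weights,
        )
        kpls = KernelPLS(
            width=kernel.width_s,
            n_components=kernel.n_components_p,
            tol=kernel.tol,
            max_iter=kernel.max_iter,
        ).fit(fm, lv)
        wv = relieff_weights(
            kpls.reconstruction_, lv, k_neighbors=self.relieff_k_neighbors
        )
        provenance = {
            "kernel": {"width_s": kpls.width_, "n_components": kpls.n_components_},
            "relieff": {"k_neighbors": self.relieff_k_neighbors},
        }
        report, trace = mwmr_select(fm, wv, mwmr, provenance=provenance)
        report.method = "kpls-mwmr"
        self.kpls_ = kpls
        self.weight_vector_ = wv
        self.weights_ = wv.weights
        self.report_ = report
        self.trace_ = trace
        self.selected_names_ = report.feature_names
        self.ranking_ = np.array(
            [fm.feature_names.index(nm) for nm in report.feature_names]
        )
        self.support_ = np.zeros(fm.n_features, dtype=bool)
        self.support_[self.ranking_] = True
        return self


class ReliefFSelector(_TopKSelectorBase):
    """Top-k filter by ReliefF weights on the raw features."""

    def __init__(self, n_features_to_select: int = 3, k_neighbors: int = 10):
        self.n_features_to_select = n_features_to_select
        self.k_neighbors = k_neighbors

    def _weight(self, fm: FeatureMatrix, lv: LabelVector) -> WeightVector:
        return relieff_weights(fm, lv, k_neighbors=self.k_neighbors)

    def fit(self, X, y):
        fm, lv = self._prepare(X, y)
        k = self._check_k(self.n_features_to_select, fm.n_features)
        wv = self._weight(fm, lv)
        self.weight_vector_ = wv
        self.weights_ = wv.weights
        self.ranking_ = wv.ranking()[:k]
        self.selected_names_ = [fm.feature_names[j] for j in self.ranking_]
        self.support_ = np.zeros(fm.n_features, dtype=bool)
        self.support_[self.ranking_] = True
        return self


class FisherScoreSelector(ReliefFSelector):
    """Top-k filter by Fisher score (between/within class variance ratio)."""

    def __init__(self, n_features_to_select: int = 3):
        self.n_features_to_select = n_features_to_select

    def _weight(self, fm: FeatureMatrix, lv: LabelVector) -> WeightVector:
        return fisher_weights(fm, lv)
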