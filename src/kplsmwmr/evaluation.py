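"""Cross-validated evaluation of selected feature subsets.

Protocol: repeated stratified k-fold cross-validation (default 10 folds,
10 repeats) of a linear SVM (C = 1) trained on the selected columns only.
Three metrics are computed per held-out fold from its confusion matrix —
accuracy, Cohen's kappa and macro-F1 — and averaged over folds x repeats
(fold-averaged, not pooled).

Selection can be performed once on the full data (``select_once``,
matching benchmark-style tables where the subset is fixed up front) or
re-run inside every training split (``within_fold``, the leakage-safe
default for honest generalization estimates).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from sklearn.base import clone
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .io import ConfigurationError, FeatureMatrix, LabelVector
from .kpls import KernelConfig
from .selection import MWMRConfig, run_pipeline

__all__ = [
    "EvalConfig",
    "FoldResult",
    "EvalReport",
    "cohens_kappa",
    "macro_f1",
    "confusion_matrix",
    "cross_validate",
    "alpha_sweep",
]


@dataclass
class EvalConfig:
    n_folds: int = 10
    n_repeats: int = 10
    classifier: object = None  # fit(X, y)/predict(X) contract; default linear SVM C=1
    seed: int = 0
    selection_mode: str = "within_fold"

    def __post_init__(self) -> None:
        if self.n_folds < 2:
            raise ConfigurationError("n_folds must be >= 2")
        if self.n_repeats < 1:
            raise ConfigurationError("n_repeats must be >= 1")
        if self.selection_mode not in {"within_fold", "select_once"}:
            raise ConfigurationError(
                f"selection_mode must be within_fold/select_once, got {self.selection_mode!r}"
            )

    def make_classifier(self):
        proto = self.classifier if self.classifier is not None else SVC(kernel="linear", C=1.0)
        try:
            return clone(proto)
        except TypeError:
            import copy

            return copy.deepcopy(proto)


@dataclass
class FoldResult:
    repeat: int
    fold: int
    accuracy: float
    kappa: float
    macro_f1: float
    confusion: np.ndarray
    selected: list[str]


@dataclass
class EvalReport:
    folds: list[FoldResult]
    classes: list
    aggregate: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.aggregate:
            for metric in ("accuracy", "kappa", "macro_f1"):
                vals = np.array([getattr(f, metric) for f in self.folds])
                self.aggregate[metric] = {
                    "mean": float(vals.mean()),
                    "sd": float(vals.std(ddof=1)) if len(vals) > 1 else 0.0,
                }

    @property
    def mean_accuracy(self) -> float:
        return self.aggregate["accuracy"]["mean"]


def confusion_matrix(
    y_true: np.ndarray, y_pred: np.ndarray, classes: Sequence
) -> np.ndarray:
    """q x q count matrix, rows = true class, columns = predicted class."""
    lookup = {c: i for i, c in enumerate(classes)}
    M = np.zeros((len(classes), len(classes)), dtype=int)
    for t, p in zip(np.asarray(y_true).tolist(), np.asarray(y_pred).tolist()):
        M[lookup[t], lookup[p]] += 1
    return M


def cohens_kappa(confusion: np.ndarray) -> float:
    """Chance-corrected agreement (p0 - pe)/(1 - pe) from a confusion matrix.

    p0 is the overall accuracy trace/N and pe the accuracy expected by
    chance from the marginals. The degenerate pe = 1 case (all mass in a
    single row-column cell) is defined as 0 with a warning.
    """
    M = np.asarray(confusion, dtype=float)
    N = M.sum()
    if N < 1:
        raise ConfigurationError("empty confusion matrix")
    p0 = np.trace(M) / N
    pe = float((M.sum(axis=1) * M.sum(axis=0)).sum()) / N**2
    if pe >= 1.0:
        warnings.warn("degenerate confusion matrix (pe = 1); kappa defined as 0", stacklevel=2)
        return 0.0
    return float((p0 - pe) / (1.0 - pe))


def macro_f1(confusion: np.ndarray) -> float:
    """Unweighted mean over classes of 2PR/(P+R); undefined class F1 counts 0."""
    M = np.asarray(confusion, dtype=float)
    if M.sum() < 1:
        raise ConfigurationError("empty confusion matrix")
    f1s = []
    for c in range(M.shape[0]):
        tp = M[c, c]
        prec_den = M[:, c].sum()
        rec_den = M[c, :].sum()
        p = tp / prec_den if prec_den > 0 else 0.0
        r = tp / rec_den if rec_den > 0 else 0.0
        f1s.append(2 * p * r / (p + r) if (p + r) > 0 else 0.0)
    return float(np.mean(f1s))


SelectorCallback = Callable[[FeatureMatrix, LabelVector], Sequence[str]]


def cross_validate(
    X: FeatureMatrix,
    y: LabelVector,
    selected: Sequence[str] | SelectorCallback,
    config: EvalConfig | None = None,
) -> EvalReport:
    """Repeated stratified k-fold evaluation of a feature subset.

    ``selected`` is either a fixed list of feature names (mode
    ``select_once``) or a callback ``(X_train, y_train) -> names`` re-run
    on every training split (required for mode ``within_fold``; the test
    split never reaches it). Fold assignment is seeded per repeat, so the
    whole report is reproducible from ``config.seed``.
    """
    config = config or EvalConfig()
    n = X.n_samples
    if len(y) != n:
        raise ConfigurationError(f"{len(y)} labels for {n} samples")
    counts = [int((y.labels == c).sum()) for c in y.classes]
    if min(counts) < config.n_folds:
        raise ConfigurationError(
            f"class {y.classes[int(np.argmin(counts))]!r} has {min(counts)} members, "
            f"fewer than n_folds={config.n_folds}; use fewer folds"
        )
    callback = callable(selected)
    if config.selection_mode == "within_fold" and not callback:
        raise ConfigurationError(
            "within_fold mode requires a selector callback so selection is "
            "re-run on each training split (no leakage)"
        )
    if not callback:
        fixed = list(selected)
        if not fixed:
            raise ConfigurationError("selected feature list is empty")
        missing = set(fixed) - set(X.feature_names)
        if missing:
            raise ConfigurationError(f"unknown feature names: {sorted(missing)}")

    label_arr = y.labels
    results: list[FoldResult] = []
    for rep in range(config.n_repeats):
        skf = StratifiedKFold(
            n_splits=config.n_folds, shuffle=True, random_state=config.seed + rep
        )
        for fold, (tr, te) in enumerate(skf.split(np.zeros(n), label_arr)):
            X_tr = FeatureMatrix(
                X.values[tr], X.feature_names, [X.sample_ids[i] for i in tr]
            )
            y_tr = y.subset(tr)
            names = list(selected(X_tr, y_tr)) if callback else fixed
            cols = [X.feature_names.index(nm) for nm in names]
            clf = config.make_classifier()
            clf.fit(X.values[np.ix_(tr, cols)], label_arr[tr])
            pred = clf.predict(X.values[np.ix_(te, cols)])
            M = confusion_matrix(label_arr[te], pred, y.classes)
            results.append(
                FoldResult(
                    repeat=rep,
                    fold=fold,
                    accuracy=float(np.trace(M) / M.sum()),
                    kappa=cohens_kappa(M),
                    macro_f1=macro_f1(M),
                    confusion=M,
                    selected=names,
                )
            )
    return EvalReport(folds=results, classes=list(y.classes))


def alpha_sweep(
    X: FeatureMatrix,
    y: LabelVector,
    alphas: Sequence[float],
    k: int,
    eval_config: EvalConfig | None = None,
    kernel: KernelConfig | None = None,
    relieff_k_neighbors: int = 10,
    redundancy_aggregate: str = "mean",
    redundancy_target: str = "pool",
) -> list[dict]:
    """Accuracy of the full pipeline at each alpha, sorted by alpha.

    In ``select_once`` mode the pipeline runs once per alpha on the full
    data and the fixed subset is cross-validated; in ``within_fold`` mode
    the pipeline is re-run inside every training split.
    """
    eval_config = eval_config or EvalConfig(selection_mode="select_once")
    rows = []
    for alpha in sorted(alphas):
        if not 0.0 <= alpha <= 1.0:
            raise ConfigurationError(f"alpha must be in [0,1], got {alpha}")
        mwmr = MWMRConfig(
            alpha=alpha,
            k=k,
            redundancy_aggregate=redundancy_aggregate,
            redundancy_target=redundancy_target,
        )

        def selector(X_tr: FeatureMatrix, y_tr: LabelVector, _mwmr=mwmr):
            report, _ = run_pipeline(
                X_tr, y_tr, kernel=kernel, mwmr=_mwmr,
                relieff_k_neighbors=relieff_k_neighbors,
            )
            return report.feature_names

        if eval_config.selection_mode == "select_once":
            report, _ = run_pipeline(
                X, y, kernel=kernel, mwmr=mwmr, relieff_k_neighbors=relieff_k_neighbors
            )
            ev = cross_validate(X, y, report.feature_names, eval_config)
            selected_names = report.feature_names
        else:
            ev = cross_validate(X, y, selector, eval_config)
            selected_names = None
        rows.append(
            {
                "alpha": float(alpha),
                "k": k,
                "mean_accuracy": ev.aggregate["accuracy"]["mean"],
                "sd_accuracy": ev.aggregate["accuracy"]["sd"],
                "mean_kappa": ev.aggregate["kappa"]["mean"],
                "mean_macro_f1": ev.aggregate["macro_f1"]["mean"],
                "selected": selected_names,
            }
        )
    return rows
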