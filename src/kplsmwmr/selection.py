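"""Greedy maximum-weight / minimum-redundancy feature selection.

A candidate feature j is scored by

    R_j = alpha * w_j - (1 - alpha) * r_j

where w_j is its (min-max normalized) relevance weight and r_j aggregates
the absolute Pearson correlation of the candidate with a redundancy
target set. The weight factor alpha in [0, 1] tunes the trade-off:
alpha = 1 reduces to pure weight ranking, alpha = 0 to pure redundancy
minimization after the first pick. Selection is greedy forward: the first
feature is the weight argmax, each later step takes the criterion argmax
over the remaining pool.

Two redundancy targets are supported. ``"pool"`` (default) measures the
candidate against the other *non-selected* candidates, so correlated but
informative features are not penalized against each other; ``"selected"``
measures it against the already-selected set, the convention of the wider
minimum-redundancy literature (and the mode in which duplicated features
are provably never picked twice at small alpha). See docs/methods.md for
the trade-off.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._version import __version__ as _pkg_version
from .io import (
    ConfigurationError,
    FeatureMatrix,
    LabelVector,
    SelectedFeature,
    SelectionReport,
)
from .kpls import KernelConfig, KernelPLS
from .weighting import WeightVector, relieff_weights

__all__ = [
    "MWMRConfig",
    "SelectionStep",
    "SelectionTrace",
    "pearson_r",
    "redundancy_score",
    "mwmr_select",
    "run_pipeline",
]


@dataclass
class MWMRConfig:
    """Greedy-criterion settings: trade-off alpha, subset size k, and how
    per-candidate redundancy is aggregated (mean/max/min of |r|) and
    against which set (pool or selected)."""

    alpha: float = 0.3
    k: int = 3
    redundancy_aggregate: str = "mean"
    redundancy_target: str = "pool"
    normalize_weights: bool = True

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha <= 1.0:
            raise ConfigurationError(f"alpha must be in [0,1], got {self.alpha}")
        if self.k < 1:
            raise ConfigurationError(f"k must be >= 1, got {self.k}")
        if self.redundancy_aggregate not in {"mean", "max", "min"}:
            raise ConfigurationError(
                f"redundancy_aggregate must be mean/max/min, got {self.redundancy_aggregate!r}"
            )
        if self.redundancy_target not in {"pool", "selected"}:
            raise ConfigurationError(
                f"redundancy_target must be pool/selected, got {self.redundancy_target!r}"
            )


@dataclass
class SelectionStep:
    step: int
    candidate_pool_size: int
    chosen_feature: str
    weight_used: float
    redundancy_used: float
    criterion_R: float


@dataclass
class SelectionTrace:
    steps: list[SelectionStep] = field(default_factory=list)

    def __iter__(self):
        return iter(self.steps)

    def __len__(self) -> int:
        return len(self.steps)


def pearson_r(a: np.ndarray, b: np.ndarray) -> float:
    """Sample Pearson correlation; 0 by convention if either side is constant."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ConfigurationError(f"length mismatch: {a.shape} vs {b.shape}")
    if len(a) < 2:
        raise ConfigurationError("need at least 2 observations")
    ac = a - a.mean()
    bc = b - b.mean()
    sa = np.sqrt(ac @ ac)
    sb = np.sqrt(bc @ bc)
    if sa == 0.0 or sb == 0.0:
        return 0.0
    return float(np.clip((ac @ bc) / (sa * sb), -1.0, 1.0))


def redundancy_score(candidate, selected, aggregate: str = "mean") -> float:
    """Aggregate |pearson_r(candidate, f)| over f in ``selected``; empty -> 0."""
    vectors = list(selected)
    if not vectors:
        return 0.0
    rs = [abs(pearson_r(candidate, v)) for v in vectors]
    agg = {"mean": np.mean, "max": np.max, "min": np.min}[aggregate]
    return float(agg(rs))


def _abs_corr_matrix(values: np.ndarray) -> np.ndarray:
    """|Pearson| matrix with zero-variance columns correlating 0 with everything."""
    Xc = values - values.mean(axis=0)
    norms = np.sqrt((Xc**2).sum(axis=0))
    ok = norms > 0.0
    safe = np.where(ok, norms, 1.0)
    C = np.abs((Xc / safe).T @ (Xc / safe))
    C = np.clip(C, 0.0, 1.0)
    C[~ok, :] = 0.0
    C[:, ~ok] = 0.0
    return C


def mwmr_select(
    X: FeatureMatrix,
    weights: WeightVector,
    config: MWMRConfig,
    provenance: dict | None = None,
) -> tuple[SelectionReport, SelectionTrace]:
    """Run the greedy selection and return the ordered subset with its trace.

    Ties on the criterion break by higher raw weight, then lower column
    index — fully deterministic across platforms.
    """
    m = X.n_features
    if len(weights) != m:
        raise ConfigurationError(f"{len(weights)} weights for {m} features")
    if config.k > m:
        raise ConfigurationError(f"k={config.k} exceeds m={m} features")
    raw = weights.weights
    w = weights.normalized if config.normalize_weights else raw
    C = _abs_corr_matrix(X.values)

    selected: list[int] = []
    pool = list(range(m))
    agg = {"mean": np.mean, "max": np.max, "min": np.min}[config.redundancy_aggregate]
    steps: list[SelectionStep] = []

    def redundancy(j: int) -> float:
        if config.redundancy_target == "selected":
            others = selected
        else:
            others = [q for q in pool if q != j]
        if not others:
            return 0.0
        return float(agg(C[j, others]))

    for step in range(config.k):
        pool_size = len(pool)
        if step == 0:
            scored = [(w[j], raw[j], -j, 0.0, j) for j in pool]
            _, _, _, r_best, best = max(scored)
            crit = float(w[best])
        else:
            scored = []
            for j in pool:
                r_j = redundancy(j)
                R_j = config.alpha * w[j] - (1.0 - config.alpha) * r_j
                scored.append((R_j, raw[j], -j, r_j, j))
            R_best, _, _, r_best, best = max(scored)
            crit = float(R_best)
        selected.append(best)
        pool.remove(best)
        steps.append(
            SelectionStep(
                step=step + 1,
                candidate_pool_size=pool_size,
                chosen_feature=X.feature_names[best],
                weight_used=float(w[best]),
                redundancy_used=float(r_best),
                criterion_R=crit,
            )
        )

    prov = dict(provenance or {})
    prov.setdefault("tool", "kplsmwmr")
    prov.setdefault("version", _pkg_version)
    prov.setdefault(
        "mwmr",
        {
            "alpha": config.alpha,
            "k": config.k,
            "redundancy_aggregate": config.redundancy_aggregate,
            "redundancy_target": config.redundancy_target,
            "normalize_weights": config.normalize_weights,
            "weighting": weights.method,
        },
    )
    report = SelectionReport(
        method=f"mwmr-{weights.method}",
        alpha=config.alpha,
        k=config.k,
        selected=[
            SelectedFeature(
                name=s.chosen_feature,
                weight=s.weight_used,
                redundancy=s.redundancy_used,
                criterion=s.criterion_R,
            )
            for s in steps
        ],
        provenance=prov,
    )
    return report, SelectionTrace(steps)


def run_pipeline(
    X: FeatureMatrix,
    y: LabelVector,
    kernel: KernelConfig | None = None,
    mwmr: MWMRConfig | None = None,
    relieff_k_neighbors: int = 10,
) -> tuple[SelectionReport, SelectionTrace]:
    """Full selector: Gram -> centering -> latent scores -> rank-p
    reconstruction -> ReliefF weights -> greedy MWMR on the original
    features. Deterministic given the configs."""
    kernel = kernel or KernelConfig()
    mwmr = mwmr or MWMRConfig()

    def _stage(name, fn):
        try:
            return fn()
        except (ConfigurationError, ValueError) as exc:
            raise type(exc)(f"[{name}] {exc}") from exc

    kpls = _stage(
        "kernel-pls",
        lambda: KernelPLS(
            width=kernel.width_s,
            n_components=kernel.n_components_p,
            tol=kernel.tol,
            max_iter=kernel.max_iter,
        ).fit(X, y),
    )
    wv = _stage(
        "relieff",
        lambda: relieff_weights(kpls.reconstruction_, y, k_neighbors=relieff_k_neighbors),
    )
    provenance = {
        "kernel": {
            "width_s": kpls.width_,
            "n_components": kpls.n_components_,
            "tol": kernel.tol,
            "max_iter": kernel.max_iter,
        },
        "relieff": {"k_neighbors": relieff_k_neighbors},
    }
    report, trace = _stage(
        "mwmr-select", lambda: mwmr_select(X, wv, mwmr, provenance=provenance)
    )
    report.method = "kpls-mwmr"
    return report, trace
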