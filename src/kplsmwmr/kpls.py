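"""Kernel partial least squares latent extraction.

The latent mapping maximizes, component by component, the covariance
between the kernel-mapped inputs and a centered one-hot label indicator:
with centered Gram matrix K and indicator Y the score iteration

    t <- K u / ||K u||,   c <- Y' t,   u <- Y c / ||Y c||

is a power iteration on K Y Y'; after convergence both K and Y are
deflated by the projector (I - t t') and the next component is extracted.
Scores are orthonormal by construction. The per-feature "latent
reconstruction" T T' Xc + column means restores the original feature
dimensionality (rank-p smoothed copy of X) so that per-feature relevance
weights can be computed downstream.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist, pdist

from .io import ConfigurationError, FeatureMatrix, LabelVector

__all__ = [
    "KernelConfig",
    "KPLSModel",
    "gaussian_gram",
    "median_width",
    "center_gram",
    "label_indicator",
    "fit_kpls",
    "latent_reconstruct",
    "KernelPLS",
]


@dataclass
class KernelConfig:
    """Gaussian-kernel and iteration settings.

    ``width_s`` is the kernel scale in K(x, y) = exp(-||x - y||^2 / s);
    the string ``"median"`` selects the median of all pairwise squared
    distances (deterministic, scale-adaptive default).
    """

    width_s: float | str = "median"
    n_components_p: int = 20
    tol: float = 1e-8
    max_iter: int = 500

    def __post_init__(self) -> None:
        if isinstance(self.width_s, str):
            if self.width_s != "median":
                raise ConfigurationError(
                    f"width_s must be positive or 'median', got {self.width_s!r}"
                )
        elif self.width_s <= 0:
            raise ConfigurationError("width_s must be positive")
        if self.n_components_p < 1:
            raise ConfigurationError("n_components_p must be positive")
        if self.tol <= 0 or self.max_iter < 1:
            raise ConfigurationError("tol must be > 0 and max_iter >= 1")


@dataclass
class KPLSModel:
    """Fitted latent model: Gram matrix, scores and reconstruction pieces."""

    gram_K: np.ndarray
    scores_T: np.ndarray
    y_indicator: np.ndarray
    column_means: np.ndarray
    latent_reconstruction: np.ndarray
    width_s: float
    n_components: int
    n_iter: list = field(default_factory=list)
    converged: list = field(default_factory=list)


def _as_array(X) -> np.ndarray:
    if isinstance(X, FeatureMatrix):
        return X.values
    return np.asarray(X, dtype=float)


def gaussian_gram(X, width_s: float) -> np.ndarray:
    """Gaussian Gram matrix K[i,j] = exp(-||x_i - x_j||^2 / width_s)."""
    if width_s <= 0:
        raise ConfigurationError(f"kernel width must be positive, got {width_s}")
    Xa = _as_array(X)
    D2 = cdist(Xa, Xa, "sqeuclidean")
    K = np.exp(-D2 / width_s)
    # exact symmetry and unit diagonal despite floating-point cdist noise
    K = (K + K.T) / 2.0
    np.fill_diagonal(K, 1.0)
    return K


def median_width(X) -> float:
    """Median of the n(n-1)/2 pairwise squared Euclidean distances."""
    Xa = _as_array(X)
    if Xa.shape[0] < 2:
        raise ConfigurationError("median width needs at least 2 samples")
    d2 = pdist(Xa, "sqeuclidean")
    med = float(np.median(d2))
    if med == 0.0:
        raise ConfigurationError(
            "median pairwise distance is zero (too many identical samples); "
            "the Gaussian kernel is degenerate — supply width_s explicitly"
        )
    return med


def center_gram(K: np.ndarray) -> np.ndarray:
    """Double-center a Gram matrix: (I - J/n) K (I - J/n)."""
    K = np.asarray(K, dtype=float)
    if K.ndim != 2 or K.shape[0] != K.shape[1]:
        raise ConfigurationError(f"Gram matrix must be square, got shape {K.shape}")
    row = K.mean(axis=0, keepdims=True)
    col = K.mean(axis=1, keepdims=True)
    return K - row - col + K.mean()


def label_indicator(y: LabelVector | np.ndarray) -> np.ndarray:
    """Column-centered one-hot encoding of the labels (n x q)."""
    if isinstance(y, LabelVector):
        idx, q = y.class_indices(), y.n_classes
    else:
        ya = np.asarray(y)
        classes = sorted(set(ya.tolist()))
        lookup = {c: i for i, c in enumerate(classes)}
        idx = np.array([lookup[v] for v in ya.tolist()])
        q = len(classes)
    if q < 2:
        raise ConfigurationError("need at least 2 classes for the label indicator")
    Y = np.eye(q)[idx]
    return Y - Y.mean(axis=0)


def _numerical_rank(K: np.ndarray) -> int:
    ev = np.linalg.eigvalsh((K + K.T) / 2.0)
    top = ev[-1]
    if top <= 0:
        return 0
    return int((ev > len(ev) * np.finfo(float).eps * top).sum())


def fit_kpls(
    K_centered: np.ndarray,
    Y: np.ndarray,
    n_components: int = 20,
    tol: float = 1e-8,
    max_iter: int = 500,
) -> tuple[np.ndarray, list[int], list[bool]]:
    """Extract orthonormal score vectors from a centered Gram matrix.

    ``Y`` is the (centered) label indicator. The requested number of
    components is clipped to n - 1 and to the numerical rank of K; a
    component whose inner loop exhausts ``max_iter`` is accepted as-is
    with a warning. Deterministic: u is initialized to the first column
    of the current (deflated) Y.

    Returns ``(T, n_iter, converged)`` where T is n x p with T'T = I.
    """
    K = np.asarray(K_centered, dtype=float).copy()
    Y = np.asarray(Y, dtype=float).copy()
    n = K.shape[0]
    p_max = min(n_components, n - 1, _numerical_rank(K))
    if p_max < n_components:
        warnings.warn(
            f"clipping components from {n_components} to {p_max} "
            "(sample count / Gram rank limit)",
            stacklevel=2,
        )
    scores, n_iter, converged = [], [], []
    for _ in range(p_max):
        u = Y[:, 0].copy()
        nu = np.linalg.norm(u)
        if nu < 1e-12:
            # label residual exhausted; no direction left to chase
            break
        u /= nu
        t_old = None
        ok = False
        it = 0
        for it in range(1, max_iter + 1):
            t = K @ u
            nt = np.linalg.norm(t)
            if nt < 1e-12:
                break
            t = t / nt
            c = Y.T @ t
            u_new = Y @ c
            nu = np.linalg.norm(u_new)
            if nu < 1e-12:
                break
            u = u_new / nu
            if t_old is not None and np.linalg.norm(t - t_old) < tol:
                ok = True
                break
            t_old = t
        if np.linalg.norm(K @ u) < 1e-10:
            break
        t = K @ u
        t /= np.linalg.norm(t)
        if not ok:
            warnings.warn(
                f"score iteration did not converge in {max_iter} iterations; "
                "accepting the current direction",
                stacklevel=2,
            )
        # deflate both blocks by the projector complement of t
        Kt = K @ t
        K -= np.outer(t, Kt) + np.outer(Kt, t) - np.outer(t, t) * (t @ Kt)
        Y -= np.outer(t, t @ Y)
        scores.append(t)
        n_iter.append(it)
        converged.append(ok)
    T = np.array(scores).T if scores else np.zeros((n, 0))
    return T, n_iter, converged


def latent_reconstruct(
    scores_T: np.ndarray, X, column_means: np.ndarray | None = None
) -> np.ndarray:
    """Rank-p reconstruction T T' Xc + column means (same shape as X)."""
    Xa = _as_array(X)
    T = np.asarray(scores_T, dtype=float)
    if T.shape[0] != Xa.shape[0]:
        raise ConfigurationError(
            f"scores have {T.shape[0]} rows but X has {Xa.shape[0]} samples"
        )
    mu = Xa.mean(axis=0) if column_means is None else np.asarray(column_means)
    Xc = Xa - mu
    return T @ (T.T @ Xc) + mu


class KernelPLS:
    """Gaussian-kernel PLS latent extractor with a fit/attribute surface.

    Parameters mirror :class:`KernelConfig`. After :meth:`fit`, exposes
    ``width_``, ``gram_``, ``gram_centered_``, ``x_scores_`` (orthonormal,
    n x p), ``y_indicator_``, ``n_components_``, ``column_means_`` and
    ``reconstruction_`` (the rank-p feature-space copy of the training X).
    """

    def __init__(
        self,
        width: float | str = "median",
        n_components: int = 20,
        tol: float = 1e-8,
        max_iter: int = 500,
    ):
        self.width = width
        self.n_components = n_components
        self.tol = tol
        self.max_iter = max_iter

    def get_params(self, deep: bool = True) -> dict:
        return {
            "width": self.width,
            "n_components": self.n_components,
            "tol": self.tol,
            "max_iter": self.max_iter,
        }

    def set_params(self, **params) -> "KernelPLS":
        for k, v in params.items():
            if k not in self.get_params():
                raise ConfigurationError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit(self, X, y) -> "KernelPLS":
        config = KernelConfig(
            width_s=self.width,
            n_components_p=self.n_components,
            tol=self.tol,
            max_iter=self.max_iter,
        )
        Xa = _as_array(X)
        self.width_ = (
            median_width(Xa) if config.width_s == "median" else float(config.width_s)
        )
        self.gram_ = gaussian_gram(Xa, self.width_)
        self.gram_centered_ = center_gram(self.gram_)
        self.y_indicator_ = label_indicator(y)
        T, n_iter, converged = fit_kpls(
            self.gram_centered_,
            self.y_indicator_,
            n_components=config.n_components_p,
            tol=config.tol,
            max_iter=config.max_iter,
        )
        self.x_scores_ = T
        self.n_components_ = T.shape[1]
        self.n_iter_ = n_iter
        self.converged_ = converged
        self.column_means_ = Xa.mean(axis=0)
        self.reconstruction_ = latent_reconstruct(T, Xa, self.column_means_)
        return self

    def model(self) -> KPLSModel:
        """Bundle the fitted state into a :class:`KPLSModel` record."""
        return KPLSModel(
            gram_K=self.gram_,
            scores_T=self.x_scores_,
            y_indicator=self.y_indicator_,
            column_means=self.column_means_,
            latent_reconstruction=self.reconstruction_,
            width_s=self.width_,
            n_components=self.n_components_,
            n_iter=self.n_iter_,
            converged=self.converged_,
        )
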