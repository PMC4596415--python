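"""Kernel partial least squares and per-feature importance weights.

Kernel PLS extracts, from a (double-centered) sample-by-sample kernel
matrix, a small number of orthonormal score components that maximally
covary with the binary class response.  The kernel NIPALS recursion used
here deflates both the kernel and the response after each component:

    t_a  =  K_res y_res / ||K_res y_res||        (unit-norm score)
    q_a  =  t_a' y_res                           (response loading)
    K_res <- (I - t_a t_a') K_res (I - t_a t_a')
    y_res <- y_res - q_a t_a

With a linear kernel this reproduces classical NIPALS PLS1 component
scores on centered data exactly (up to sign).

Feature importance for ranking is the response-loading-weighted squared
covariance between each (centered, unit-norm) feature column and the
score components:

    weight_j = sum_a q_a^2 (x_tilde_j' t_a)^2

a VIP-style projection score; zero-variance columns get weight 0.  This
formula is deliberately isolated in :func:`feature_weights` so an
alternative can be substituted behind the same interface.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Union

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .features import FeatureMatrix

__all__ = [
    "KernelSpec",
    "KplsModel",
    "FeatureWeights",
    "compute_kernel",
    "fit_kpls",
    "feature_weights",
    "select_top",
]

logger = logging.getLogger(__name__)


@dataclass
class KernelSpec:
    """Kernel choice for KPLS: 'linear' or 'gaussian'.

    For the gaussian kernel, ``gamma`` is either a positive number or
    the string ``"median-heuristic"`` (1 / median nonzero pairwise
    squared distance), resolved at kernel-computation time.
    """

    kind: str = "gaussian"
    gamma: Union[float, str] = "median-heuristic"

    def __post_init__(self):
        if self.kind not in ("linear", "gaussian"):
            raise ValueError(f"kernel kind must be 'linear' or 'gaussian', got {self.kind!r}")

    def resolve_gamma(self, X: np.ndarray) -> float:
        if isinstance(self.gamma, (int, float)):
            if self.gamma <= 0:
                raise ValueError("gamma must be positive")
            return float(self.gamma)
        if self.gamma != "median-heuristic":
            raise ValueError(f"unknown gamma setting {self.gamma!r}")
        sq = pdist(X, metric="sqeuclidean")
        nonzero = sq[sq > 0]
        if nonzero.size == 0:
            logger.warning(
                "all sample rows identical; gaussian median heuristic undefined, "
                "falling back to gamma = 1"
            )
            return 1.0
        return 1.0 / float(np.median(nonzero))


@dataclass
class KplsModel:
    """Fitted kernel PLS decomposition."""

    n_components: int
    scores: np.ndarray           # N x A, orthonormal columns t_a
    loadings: np.ndarray         # length A, response loadings q_a
    residual_response: np.ndarray
    response_mean: float
    kernel_spec: KernelSpec
    gamma: Optional[float] = None


@dataclass
class FeatureWeights:
    """Non-negative importance weight per feature name."""

    weights: dict[str, float] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.weights)

    def __getitem__(self, name: str) -> float:
        return self.weights[name]

    def items(self):
        return self.weights.items()


def compute_kernel(F: Union[FeatureMatrix, np.ndarray], spec: KernelSpec) -> np.ndarray:
    """Evaluate the N x N kernel matrix over sample rows.

    linear: K_ab = <x_a, x_b>; gaussian: K_ab = exp(-gamma ||x_a - x_b||^2).
    """
    X = F.values if isinstance(F, FeatureMatrix) else np.asarray(F, dtype=np.float64)
    if X.shape[0] < 2:
        raise ValueError("kernel requires at least 2 samples")
    if spec.kind == "linear":
        return X @ X.T
    gamma = spec.resolve_gamma(X)
    sq = squareform(pdist(X, metric="sqeuclidean"))
    return np.exp(-gamma * sq)


def _double_center(K: np.ndarray) -> np.ndarray:
    N = K.shape[0]
    H = np.eye(N) - np.full((N, N), 1.0 / N)
    return H @ K @ H


def fit_kpls(
    F: FeatureMatrix,
    n_components: Optional[int] = None,
    spec: Optional[KernelSpec] = None,
) -> KplsModel:
    """Fit kernel PLS between a labeled feature matrix and its response.

    The kernel is double-centered and the response mean removed; up to
    ``n_components`` (default ``min(5, N-1)``) orthonormal score
    components are extracted by kernel NIPALS with deflation.  Extraction
    stops early if the deflated kernel no longer covaries with the
    residual response.
    """
    if spec is None:
        spec = KernelSpec()
    if F.labels is None:
        raise ValueError("fit_kpls requires a labeled feature matrix")
    y = F.labels.astype(np.float64)
    N = y.size
    if np.unique(y).size < 2:
        raise ValueError("response has zero variance (all samples in one class)")
    if n_components is None:
        n_components = min(5, N - 1)
    if not 1 <= n_components <= N - 1:
        raise ValueError(f"n_components must be in [1, {N - 1}], got {n_components}")

    X = F.values
    gamma = spec.resolve_gamma(X) if spec.kind == "gaussian" else None
    K = compute_kernel(F, spec if gamma is None else KernelSpec("gaussian", gamma))
    K_res = _double_center(K)
    y_mean = float(y.mean())
    y_res = y - y_mean

    scores = np.zeros((N, n_components))
    loadings = np.zeros(n_components)
    a_done = 0
    for a in range(n_components):
        u = K_res @ y_res
        norm = np.linalg.norm(u)
        if norm < 1e-12:
            break
        t = u / norm
        q = float(t @ y_res)
        scores[:, a] = t
        loadings[a] = q
        P = np.eye(N) - np.outer(t, t)
        K_res = P @ K_res @ P
        y_res = y_res - q * t
        a_done = a + 1
    if a_done == 0:
        # degenerate: response orthogonal to every centered kernel column
        scores = np.zeros((N, 1))
        loadings = np.zeros(1)
        a_done = 1
    return KplsModel(
        n_components=a_done,
        scores=scores[:, :a_done],
        loadings=loadings[:a_done],
        residual_response=y_res,
        response_mean=y_mean,
        kernel_spec=spec,
        gamma=gamma,
    )


def feature_weights(model: KplsModel, F: FeatureMatrix) -> FeatureWeights:
    """Importance weight per feature column from a fitted KPLS model.

    weight_j = sum_a q_a^2 (x_tilde_j' t_a)^2 with x_tilde_j the centered,
    unit-norm j-th column; constant columns get weight exactly 0.
    """
    X = F.values
    Xc = X - X.mean(axis=0, keepdims=True)
    norms = np.linalg.norm(Xc, axis=0)
    nonconst = norms > 0
    Xn = np.zeros_like(Xc)
    Xn[:, nonconst] = Xc[:, nonconst] / norms[nonconst]
    # projections: features x components
    proj = Xn.T @ model.scores
    w = (proj ** 2) @ (model.loadings ** 2)
    w[~nonconst] = 0.0
    return FeatureWeights(
        weights={name: float(val) for name, val in zip(F.feature_names, w)}
    )


def select_top(weights: FeatureWeights, n: int) -> list[str]:
    """The n feature names with largest weights.

    Ties are broken by canonical feature-name order (the insertion order
    of the weights mapping, which follows the matrix's column order), so
    selection is fully deterministic.
    """
    if not 1 <= n <= len(weights):
        raise ValueError(f"n must be in [1, {len(weights)}], got {n}")
    names = list(weights.weights)
    vals = np.array([weights.weights[nm] for nm in names])
    # stable sort on descending weight keeps canonical order among ties
    order = np.argsort(-vals, kind="stable")[:n]
    return [names[i] for i in order]
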