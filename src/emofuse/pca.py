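"""Principal component analysis by covariance eigendecomposition.

Features are standardized (training statistics), the covariance matrix
C = Xᵀ X / (n − 1) of the centered data is eigendecomposed, and the
number of retained components k is the smallest j whose cumulative
explained-variance fraction reaches 90 %.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["PCAModel", "Standardizer", "fit_pca", "transform_pca"]

CUMVAR_THRESHOLD = 0.90


@dataclass
class Standardizer:
    """Column-wise z-scoring frozen on training statistics."""

    mean: np.ndarray
    sd: np.ndarray

    @classmethod
    def fit(cls, X: np.ndarray) -> "Standardizer":
        X = np.asarray(X, dtype=float)
        sd = X.std(axis=0, ddof=1)
        sd = np.where(sd > 1e-12, sd, 1.0)  # constant columns pass through
        return cls(X.mean(axis=0), sd)

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (np.asarray(X, dtype=float) - self.mean) / self.sd


@dataclass
class PCAModel:
    feature_means: np.ndarray  # (p,)
    components: np.ndarray  # (p, k) orthonormal columns
    eigenvalues: np.ndarray  # (p,) descending
    k: int
    cumvar_k: float


def fit_pca(X: np.ndarray, threshold: float = CUMVAR_THRESHOLD) -> PCAModel:
    """Fit PCA on an n × p matrix (rows already standardized).

    Eigenpairs come from the symmetric eigendecomposition of the sample
    covariance; eigenvector sign is fixed so each column's
    largest-magnitude entry is positive. k = min{ j : Σλ₁..ⱼ/Σλ ≥ threshold }
    (all components when total variance is zero).
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need an n >= 2 by p matrix")
    means = X.mean(axis=0)
    Xc = X - means
    cov = Xc.T @ Xc / (X.shape[0] - 1)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0.0, None)
    evecs = evecs[:, order]
    # deterministic sign: largest-magnitude entry of each component positive
    for j in range(evecs.shape[1]):
        idx = np.argmax(np.abs(evecs[:, j]))
        if evecs[idx, j] < 0:
            evecs[:, j] = -evecs[:, j]

    total = evals.sum()
    if total <= 0:
        k = X.shape[1]
        cumvar_k = 1.0
    else:
        cum = np.cumsum(evals) / total
        k = int(np.searchsorted(cum, threshold - 1e-12) + 1)
        cumvar_k = float(cum[k - 1])
    return PCAModel(means, evecs[:, :k].copy(), evals, k, cumvar_k)


def transform_pca(model: PCAModel, X: np.ndarray) -> np.ndarray:
    """Project rows onto the retained components: Z = (X − mean) W_k."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != model.feature_means.size:
        raise ValueError(
            f"expected {model.feature_means.size} columns, got {X.shape[1]}"
        )
    return (X - model.feature_means) @ model.components
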