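"""PCA baseline for reducing the fused features.

Centering-only PCA (no per-column variance scaling): the top-k eigenvectors
of the 1/(m-1) sample covariance, with a fixed sign convention (the
largest-magnitude entry of each component is positive) so results are
reproducible across runs and platforms.  The retained width k defaults to
the sparse autoencoder's hidden size so the two reduction arms feed the
classifier equal-width inputs.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from sklearn.decomposition import PCA as _SkPCA

from .synthetic import ConfigurationError, DimensionError


@dataclasses.dataclass
class PCAModel:
    mean: np.ndarray  # d
    components: np.ndarray  # k x d, orthonormal rows
    eigenvalues: np.ndarray  # k, non-increasing, >= 0
    k: int


def _fix_signs(components: np.ndarray) -> np.ndarray:
    out = components.copy()
    for row in out:
        j = np.argmax(np.abs(row))
        if row[j] < 0:
            row *= -1
    return out


def fit_pca(X: np.ndarray, k: int) -> PCAModel:
    """Top-k principal axes of X (rows = samples)."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    m, d = X.shape
    if m < 2:
        raise ConfigurationError("need at least 2 samples")
    if not 1 <= k <= min(m, d):
        raise ConfigurationError(f"k={k} must satisfy 1 <= k <= min(m, d)={min(m, d)}")
    sk = _SkPCA(n_components=k, svd_solver="full")
    sk.fit(X)
    return PCAModel(
        mean=sk.mean_,
        components=_fix_signs(sk.components_),
        eigenvalues=np.clip(sk.explained_variance_, 0.0, None),
        k=k,
    )


def pca_transform(model: PCAModel, X: np.ndarray) -> np.ndarray:
    """(X - mean) projected onto the principal axes; m x k scores."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != model.mean.shape[0]:
        raise DimensionError(
            f"X has {X.shape[1]} columns, model expects {model.mean.shape[0]}"
        )
    return (X - model.mean) @ model.components.T


def pca_reconstruct(model: PCAModel, scores: np.ndarray) -> np.ndarray:
    return model.mean + np.atleast_2d(scores) @ model.components


def explained_variance_ratio(model: PCAModel, total_variance: float) -> np.ndarray:
    """Eigenvalues as fractions of the total variance of the fitted data."""
    return model.eigenvalues / total_variance


def save_pca(model: PCAModel, path) -> None:
    np.savez(
        path,
        mean=model.mean,
        components=model.components,
        eigenvalues=model.eigenvalues,
        k=np.array([model.k]),
    )


def load_pca(path) -> PCAModel:
    z = np.load(path)
    return PCAModel(
        mean=z["mean"],
        components=z["components"],
        eigenvalues=z["eigenvalues"],
        k=int(z["k"][0]),
    )
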