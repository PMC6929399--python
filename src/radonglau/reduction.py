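"""PCA dimensionality reduction at a cumulative explained-variance threshold.

The concatenated wavelet coefficients are strongly correlated (neighbouring
rho bins, overlapping angles), so the feature matrix is compressed by
principal component analysis: eigenvectors of the covariance matrix are
ordered by decreasing eigenvalue and the smallest number of leading
components whose cumulative explained-variance proportion reaches the
configured threshold (default 0.94) is kept.

Features are z-scored before the eigendecomposition because the
approximation and detail blocks live on very different scales; the scaling
is part of the fitted model and is re-applied at transform time.  When the
reduction is used inside cross-validation it must be fitted on the training
folds only (see :mod:`radonglau.classify`); a whole-dataset fit is available
as an explicit "paper mode".
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.decomposition import PCA as _SkPCA


@dataclass
class PCAModel:
    """Fitted standardize-then-PCA model.

    ``components`` holds only the kept components (rows), mutually
    orthonormal; ``explained_variance_ratio`` covers all computed
    components so the threshold bracketing can be inspected.
    """

    mean: np.ndarray
    scale: np.ndarray
    components: np.ndarray
    explained_variance_ratio: np.ndarray
    explained_variance: np.ndarray = field(repr=False)
    n_kept: int = 0
    variance_threshold: float = 0.94


def fit_pca(
    features: np.ndarray,
    variance_threshold: float = 0.94,
    standardize: bool = True,
) -> PCAModel:
    """Fit PCA keeping the fewest components reaching the variance threshold.

    Parameters
    ----------
    features:
        (n_samples, n_features) matrix; at least two samples.
    variance_threshold:
        Cumulative explained-variance fraction in (0, 1] that the kept
        components must reach.
    standardize:
        Whether to z-score each feature before the eigendecomposition.
        Zero-variance features are centered but left unscaled.
    """
    X = np.asarray(features, dtype=np.float64)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("fit_pca needs a 2-D matrix with at least 2 samples")
    if not 0.0 < variance_threshold <= 1.0:
        raise ValueError("variance_threshold must lie in (0, 1]")

    mean = X.mean(axis=0)
    if standardize:
        scale = X.std(axis=0, ddof=1)
        scale[scale == 0.0] = 1.0
    else:
        scale = np.ones(X.shape[1])
    Z = (X - mean) / scale

    if not np.any(Z):
        warnings.warn("constant feature matrix; keeping a single trivial component")
        comp = np.zeros((1, X.shape[1]))
        comp[0, 0] = 1.0
        return PCAModel(
            mean=mean,
            scale=scale,
            components=comp,
            explained_variance_ratio=np.array([1.0]),
            explained_variance=np.array([0.0]),
            n_kept=1,
            variance_threshold=variance_threshold,
        )

    pca = _SkPCA(n_components=min(X.shape[0] - 1, X.shape[1]), svd_solver="full")
    pca.fit(Z)
    evr = pca.explained_variance_ratio_
    cum = np.cumsum(evr)
    idx = np.searchsorted(cum, variance_threshold - 1e-12)
    n_kept = int(min(idx + 1, evr.size))

    return PCAModel(
        mean=mean,
        scale=scale,
        components=pca.components_[:n_kept].copy(),
        explained_variance_ratio=evr,
        explained_variance=pca.explained_variance_,
        n_kept=n_kept,
        variance_threshold=variance_threshold,
    )


def transform(model: PCAModel, features: np.ndarray) -> np.ndarray:
    """Project features onto the kept components.

    Output shape is (n_samples, n_kept).  A 1-D input is treated as a
    single sample.
    """
    X = np.atleast_2d(np.asarray(features, dtype=np.float64))
    if X.shape[1] != model.mean.size:
        raise ValueError(
            f"feature count {X.shape[1]} does not match model ({model.mean.size})"
        )
    Z = (X - model.mean) / model.scale
    return Z @ model.components.T


def inverse_transform(model: PCAModel, reduced: np.ndarray) -> np.ndarray:
    """Reconstruct (approximately) the original features from projections."""
    R = np.atleast_2d(np.asarray(reduced, dtype=np.float64))
    return R @ model.components * model.scale + model.mean
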