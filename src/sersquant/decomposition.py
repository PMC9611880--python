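"""PCA for exploratory analysis of preprocessed spectra.

Scores/loadings/explained variance via SVD of the column-mean-centered
intensity matrix. No scaling beyond centering is applied: spectra arriving
here have already been normalized by the preprocessing chain.
"""

from __future__ import annotations

import numpy as np

from .base import BaseEstimator, check_fitted


class SpectralPCA(BaseEstimator):
    """Principal component analysis of a spectra matrix.

    Attributes (after ``fit``)
    ----------
    mean_ : (n_channels,) centering vector.
    components_ : (n_components, n_channels) orthonormal loadings. Sign
        convention: the loading channel with largest absolute value is
        positive, so score/loading plots are reproducible run to run.
    scores_ : (n_samples, n_components) training scores.
    explained_variance_ratio_ : fraction of total centered variance per
        component, non-increasing.
    """

    def __init__(self, n_components: int = 2):
        self.n_components = n_components

    def fit(self, X: np.ndarray, y=None) -> "SpectralPCA":
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[0] < 2:
            raise ValueError("X must be 2-d with at least 2 spectra")
        n, p = X.shape
        k = int(self.n_components)
        if not 1 <= k <= min(n - 1, p):
            raise ValueError(
                f"n_components={k} must be in [1, min(n_samples-1, n_channels)"
                f"={min(n - 1, p)}]"
            )
        self.mean_ = X.mean(axis=0)
        Xc = X - self.mean_
        U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
        # deterministic orientation: largest-|loading| channel positive
        flip = np.sign(Vt[np.arange(Vt.shape[0]), np.argmax(np.abs(Vt), axis=1)])
        flip[flip == 0] = 1.0
        Vt = Vt * flip[:, None]
        U = U * flip[None, :]
        total_var = float(np.sum(s**2))
        self.components_ = Vt[:k]
        self.singular_values_ = s[:k]
        self.scores_ = U[:, :k] * s[:k]
        self.explained_variance_ = s[:k] ** 2 / (n - 1)
        self.explained_variance_ratio_ = (
            s[:k] ** 2 / total_var if total_var > 0 else np.zeros(k)
        )
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        """Project spectra onto the fitted components."""
        check_fitted(self, "components_")
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.mean_.size:
            raise ValueError(
                f"X has {X.shape[1]} channels, model expects {self.mean_.size}"
            )
        return (X - self.mean_) @ self.components_.T

    def fit_transform(self, X: np.ndarray, y=None) -> np.ndarray:
        return self.fit(X).scores_

    def inverse_transform(self, scores: np.ndarray) -> np.ndarray:
        """Reconstruct spectra from scores."""
        check_fitted(self, "components_")
        return np.atleast_2d(scores) @ self.components_ + self.mean_


def pca_fit(X: np.ndarray, n_components: int) -> SpectralPCA:
    """Functional wrapper: fit :class:`SpectralPCA` on a spectra matrix."""
    return SpectralPCA(n_components=n_components).fit(X)
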