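"""Spectral preprocessing: AsLS baseline correction, Savitzky-Golay
smoothing, vector normalization and standard normal variate (SNV).

Two chains are used downstream: baseline -> smooth -> vector-normalize
ahead of PCA, and SNV alone ahead of PLS calibration.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from scipy.signal import savgol_filter
from scipy.sparse.linalg import spsolve

from .base import BaseEstimator


def asls_baseline(
    y: np.ndarray,
    lam: float = 1e5,
    p: float = 0.001,
    n_iter: int = 10,
) -> tuple[np.ndarray, np.ndarray]:
    """Asymmetric least squares baseline (Eilers-Boelens style).

    The baseline z minimizes sum_i w_i (y_i - z_i)^2 + lam * sum (d2 z)^2
    with asymmetric weights w_i = p where y_i > z_i, else 1 - p, re-estimated
    for ``n_iter`` iterations. Points above the baseline (peaks) get the
    small weight p so the smooth curve hugs the spectrum from below.

    Returns
    -------
    (baseline, corrected) where corrected = y - baseline, unclipped.
    """
    y = np.asarray(y, dtype=float)
    if y.ndim != 1 or y.size < 5:
        raise ValueError("y must be a 1-d vector of length >= 5")
    if not np.all(np.isfinite(y)):
        raise ValueError("y contains non-finite values")
    if lam <= 0:
        raise ValueError("lam must be > 0")
    if not 0 < p < 1:
        raise ValueError("p must lie in (0, 1)")
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")

    n = y.size
    d2 = sp.diags([1.0, -2.0, 1.0], [0, 1, 2], shape=(n - 2, n), format="csc")
    penalty = lam * (d2.T @ d2)
    w = np.ones(n)
    z = y
    for _ in range(n_iter):
        wmat = sp.diags(w, format="csc")
        z = spsolve((wmat + penalty).tocsc(), w * y)
        w = np.where(y > z, p, 1.0 - p)
    return z, y - z


def savgol_smooth(y: np.ndarray, window: int = 9, order: int = 3) -> np.ndarray:
    """Savitzky-Golay smoothing (local polynomial least squares).

    Edge channels are served by a polynomial fit on the truncated window
    (scipy's ``mode="interp"``).
    """
    y = np.asarray(y, dtype=float)
    if window % 2 == 0 or window < 3:
        raise ValueError("window must be an odd integer >= 3")
    if order >= window:
        raise ValueError("order must be < window")
    if y.size < window:
        raise ValueError(f"need at least window={window} channels, got {y.size}")
    return savgol_filter(y, window_length=window, polyorder=order, mode="interp")


def vector_normalize(y: np.ndarray) -> np.ndarray:
    """Scale a spectrum to unit Euclidean norm."""
    y = np.asarray(y, dtype=float)
    norm = np.linalg.norm(y)
    if norm == 0:
        raise ValueError("cannot vector-normalize an all-zero spectrum")
    return y / norm


def snv(y: np.ndarray) -> np.ndarray:
    """Standard normal variate: per-spectrum centering and unit-SD scaling.

    Uses the sample standard deviation (n - 1 denominator), so
    ``snv([1, 2, 3]) == [-1, 0, 1]``.
    """
    y = np.asarray(y, dtype=float)
    if y.size < 2:
        raise ValueError("SNV needs at least 2 channels")
    sd = y.std(ddof=1)
    if sd == 0:
        raise ValueError("SNV undefined for a constant spectrum (zero variance)")
    return (y - y.mean()) / sd


@dataclass(frozen=True)
class PreprocessConfig:
    """Parameters of the two preprocessing chains.

    chain: ``"pca_chain"`` (AsLS -> Savitzky-Golay -> vector normalization),
    ``"snv_chain"`` (SNV only) or ``"none"`` (identity). AsLS defaults follow
    common Raman practice: lam 1e5, p 0.001, 10 iterations; Savitzky-Golay
    window 9, order 3.
    """

    chain: str = "snv_chain"
    asls_lambda: float = 1e5
    asls_p: float = 0.001
    asls_iterations: int = 10
    savgol_window: int = 9
    savgol_order: int = 3

    def __post_init__(self) -> None:
        if self.chain not in ("pca_chain", "snv_chain", "none"):
            raise ValueError(f"unknown chain {self.chain!r}")
        if self.asls_lambda <= 0 or not 0 < self.asls_p < 1:
            raise ValueError("invalid AsLS parameters")
        if self.asls_iterations < 1:
            raise ValueError("asls_iterations must be >= 1")
        if self.savgol_window % 2 == 0 or self.savgol_window < 3:
            raise ValueError("savgol_window must be odd and >= 3")
        if self.savgol_order >= self.savgol_window:
            raise ValueError("savgol_order must be < savgol_window")


class AsLSBaseline(BaseEstimator):
    """Transformer that removes an AsLS-estimated baseline per spectrum."""

    def __init__(self, lam: float = 1e5, p: float = 0.001, n_iter: int = 10):
        self.lam = lam
        self.p = p
        self.n_iter = n_iter

    def fit(self, X, y=None):
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return np.vstack(
            [asls_baseline(row, self.lam, self.p, self.n_iter)[1] for row in X]
        )

    def fit_transform(self, X, y=None):
        return self.fit(X, y).transform(X)


class SavGolSmoother(BaseEstimator):
    """Row-wise Savitzky-Golay smoothing transformer."""

    def __init__(self, window: int = 9, order: int = 3):
        self.window = window
        self.order = order

    def fit(self, X, y=None):
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return np.vstack([savgol_smooth(row, self.window, self.order) for row in X])

    def fit_transform(self, X, y=None):
        return self.fit(X, y).transform(X)


class VectorNormalizer(BaseEstimator):
    """Row-wise unit-L2-norm scaling transformer."""

    def fit(self, X, y=None):
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return np.vstack([vector_normalize(row) for row in X])

    def fit_transform(self, X, y=None):
        return self.fit(X, y).transform(X)


class SNVScaler(BaseEstimator):
    """Row-wise standard normal variate transformer."""

    def fit(self, X, y=None):
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return np.vstack([snv(row) for row in X])

    def fit_transform(self, X, y=None):
        return self.fit(X, y).transform(X)


def _chain_steps(config: PreprocessConfig) -> list[BaseEstimator]:
    if config.chain == "pca_chain":
        return [
            AsLSBaseline(config.asls_lambda, config.asls_p, config.asls_iterations),
            SavGolSmoother(config.savgol_window, config.savgol_order),
            VectorNormalizer(),
        ]
    if config.chain == "snv_chain":
        return [SNVScaler()]
    return []


def preprocess_matrix(X: np.ndarray, config: PreprocessConfig) -> np.ndarray:
    """Apply a preprocessing chain spectrum-by-spectrum to a matrix."""
    out = np.atleast_2d(np.asarray(X, dtype=float))
    for step in _chain_steps(config):
        out = step.fit_transform(out)
    return out


def preprocess_set(spectra, config: PreprocessConfig):
    """Apply a chain to a :class:`~sersquant.simulate.SpectraSet`.

    Metadata is passed through unchanged; failures are re-raised with the
    offending sample id attached.
    """
    from .simulate import SpectraSet  # local import avoids a cycle

    rows = []
    for i, row in enumerate(spectra.intensities):
        try:
            out = preprocess_matrix(row[None, :], config)[0]
        except ValueError as exc:
            sid = spectra.metadata.iloc[i]["sample_id"]
            raise ValueError(f"preprocessing failed for sample {sid!r}: {exc}") from exc
        rows.append(out)
    return SpectraSet(
        axis=spectra.axis.copy(),
        intensities=np.vstack(rows),
        metadata=spectra.metadata.copy(),
    )
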