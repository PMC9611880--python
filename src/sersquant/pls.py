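"""Partial least squares regression via NIPALS.

PLS1 (single response) and PLS2 (several responses modelled simultaneously)
share one code path: components are extracted by the NIPALS power iteration
on column-centered X and Y, X is deflated after each component, and the
fitted model collapses to a single linear map
``Y_hat = (X - x_mean) @ coef_ + y_mean``.

X and Y are mean-centered only — no autoscaling — so when Y carries molar
concentrations every RMSE downstream is in M.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

from .base import BaseEstimator, check_fitted

logger = logging.getLogger(__name__)

#: Hard ceiling on components considered anywhere in the package.
MAX_COMPONENTS = 15


@dataclass
class FitMetrics:
    """Figures of merit for one response.

    ``q2`` is the coefficient of determination of predictions against a
    fixed center (the training-set mean of the response); on training data
    the same quantity is conventionally called R². RMSE values inherit the
    units of the response (M for molar concentrations).
    """

    q2: float
    rmse: float
    n: int


def regression_metrics(
    y_true: np.ndarray, y_pred: np.ndarray, y_center: float
) -> FitMetrics:
    """Q²/R² and RMSE of predictions against nominal values.

    Q² = 1 - sum((y_true - y_pred)^2) / sum((y_true - y_center)^2), where
    ``y_center`` is the training-set mean of the response. A constant
    ``y_true`` equal to the center makes Q² undefined (returned as NaN with
    a warning).
    """
    y_true = np.asarray(y_true, dtype=float).ravel()
    y_pred = np.asarray(y_pred, dtype=float).ravel()
    if y_true.size != y_pred.size:
        raise ValueError("y_true and y_pred must have equal length")
    if y_true.size < 2:
        raise ValueError("need at least 2 points")
    ss_res = float(np.sum((y_true - y_pred) ** 2))
    ss_tot = float(np.sum((y_true - y_center) ** 2))
    rmse = float(np.sqrt(ss_res / y_true.size))
    if ss_tot == 0:
        warnings.warn(
            "Q2 undefined: reference values are constant and equal to the center",
            RuntimeWarning,
            stacklevel=2,
        )
        return FitMetrics(q2=float("nan"), rmse=rmse, n=y_true.size)
    return FitMetrics(q2=1.0 - ss_res / ss_tot, rmse=rmse, n=y_true.size)


class PLSNipals(BaseEstimator):
    """NIPALS partial least squares regression.

    Parameters
    ----------
    n_components:
        Number of latent variables A to extract. If the centered X (or Y)
        runs out of rank first, extraction stops early and
        ``n_components_`` records the achieved count.
    sample_weight-aware fitting is handled upstream by row replication
    (bootstrap multiplicity), keeping the core algorithm unweighted.

    Attributes (after ``fit``)
    ----------
    x_weights_ : (n_channels, A) NIPALS weight vectors W, unit norm.
    x_loadings_ : (n_channels, A) loadings P.
    y_loadings_ : (n_responses, A) loadings Q.
    x_scores_ : (n_samples, A) training scores T, mutually orthogonal.
    coef_ : (n_channels, n_responses) regression coefficients B.
    x_mean_, y_mean_ : centering vectors.
    n_components_ : components actually extracted.
    """

    #: NIPALS inner-loop convergence tolerance on the score vector.
    _tol = 1e-12
    _max_iter = 500

    def __init__(self, n_components: int = 2):
        self.n_components = n_components

    def fit(self, X: np.ndarray, Y: np.ndarray) -> "PLSNipals":
        X = np.asarray(X, dtype=float)
        Y = np.asarray(Y, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be 2-d (n_samples, n_channels)")
        self._y_1d = Y.ndim == 1
        if self._y_1d:
            Y = Y[:, None]
        if Y.shape[0] != X.shape[0]:
            raise ValueError(
                f"X has {X.shape[0]} rows but Y has {Y.shape[0]}"
            )
        n, p = X.shape
        q = Y.shape[1]
        a_req = int(self.n_components)
        if a_req < 1:
            raise ValueError("n_components must be >= 1")
        if a_req > min(n - 1, p):
            raise ValueError(
                f"n_components={a_req} exceeds min(n_samples-1, n_channels)"
                f"={min(n - 1, p)}"
            )

        self.x_mean_ = X.mean(axis=0)
        self.y_mean_ = Y.mean(axis=0)
        Xc = X - self.x_mean_
        Yc = Y - self.y_mean_

        # machine-precision floor for "no variance left", scaled to the data
        eps = np.finfo(float).eps
        x_floor = eps * max(1.0, float(np.abs(Xc).max(initial=0.0))) ** 2 * n * p

        W = np.zeros((p, a_req))
        P = np.zeros((p, a_req))
        Q = np.zeros((q, a_req))
        T = np.zeros((n, a_req))
        achieved = 0
        for a in range(a_req):
            if float(np.sum(Xc * Xc)) <= x_floor or float(np.sum(Yc * Yc)) <= x_floor:
                logger.info(
                    "NIPALS stopped early at %d of %d components (rank exhausted)",
                    achieved,
                    a_req,
                )
                break
            u = Yc[:, int(np.argmax(Yc.var(axis=0)))]
            t = np.zeros(n)
            for _ in range(self._max_iter):
                w = Xc.T @ u
                w_norm = np.linalg.norm(w)
                if w_norm == 0:
                    break
                w = w / w_norm
                t_new = Xc @ w
                qv = Yc.T @ t_new / (t_new @ t_new)
                if q == 1:
                    t = t_new
                    break
                u = Yc @ qv / (qv @ qv)
                if np.linalg.norm(t_new - t) <= self._tol * np.linalg.norm(t_new):
                    t = t_new
                    break
                t = t_new
            tt = float(t @ t)
            if tt <= x_floor:
                logger.info(
                    "NIPALS stopped early at %d of %d components (degenerate score)",
                    achieved,
                    a_req,
                )
                break
            pv = Xc.T @ t / tt
            qv = Yc.T @ t / tt
            Xc = Xc - np.outer(t, pv)
            Yc = Yc - np.outer(t, qv)
            W[:, a], P[:, a], Q[:, a], T[:, a] = w, pv, qv, t
            achieved += 1

        if achieved == 0:
            raise ValueError("X or Y has no variance; cannot fit any component")
        self.n_components_ = achieved
        self.x_weights_ = W[:, :achieved]
        self.x_loadings_ = P[:, :achieved]
        self.y_loadings_ = Q[:, :achieved]
        self.x_scores_ = T[:, :achieved]
        self.coef_ = self._coef(achieved)
        return self

    def _coef(self, a: int) -> np.ndarray:
        """Regression coefficients truncated to the first ``a`` components."""
        W = self.x_weights_[:, :a]
        P = self.x_loadings_[:, :a]
        Q = self.y_loadings_[:, :a]
        # B = W (P'W)^-1 Q'; P'W is upper triangular with unit-ish diagonal
        return W @ np.linalg.solve(P.T @ W, Q.T)

    def predict(self, X: np.ndarray, n_components: int | None = None) -> np.ndarray:
        """Predict responses; optionally with a truncated component count."""
        check_fitted(self, "coef_")
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.x_mean_.size:
            raise ValueError(
                f"X has {X.shape[1]} channels but the model was fitted on "
                f"{self.x_mean_.size}"
            )
        if n_components is None:
            coef = self.coef_
        else:
            if not 1 <= n_components <= self.n_components_:
                raise ValueError(
                    f"n_components must be in [1, {self.n_components_}]"
                )
            coef = self._coef(n_components)
        Yhat = (X - self.x_mean_) @ coef + self.y_mean_
        return Yhat.ravel() if self._y_1d else Yhat

    def predict_path(self, X: np.ndarray) -> np.ndarray:
        """Predictions for every truncation a = 1..A in one pass.

        Returns an array of shape (A, n_samples, n_responses); used by the
        cross-validation engines so one fit serves all candidate component
        counts.
        """
        check_fitted(self, "coef_")
        X = np.atleast_2d(np.asarray(X, dtype=float))
        Xc = X - self.x_mean_
        out = np.empty((self.n_components_, X.shape[0], self.y_mean_.size))
        for a in range(1, self.n_components_ + 1):
            out[a - 1] = Xc @ self._coef(a) + self.y_mean_
        return out


def pls_fit(X: np.ndarray, Y: np.ndarray, n_components: int) -> PLSNipals:
    """Functional wrapper: fit a NIPALS PLS model with A components."""
    return PLSNipals(n_components=n_components).fit(X, Y)


def pls_predict(model: PLSNipals, X_new: np.ndarray) -> np.ndarray:
    """Functional wrapper over :meth:`PLSNipals.predict`."""
    return model.predict(X_new)
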