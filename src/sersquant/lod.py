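"""Limit-of-detection estimation from multivariate calibration output.

The pseudo-univariate route: regress cross-validated PLS predictions on
nominal concentrations by ordinary least squares, take the residual
standard deviation about that line as the prediction noise, and convert it
to a concentration detection limit through the slope:

    LOD = multiplier * s_res / b

with the ICH-style multiplier 3.3 by default (3 is a common alternative).
Predictions must come from held-out (cross-validated) fits, never training
fits, or the residual spread — and hence the LOD — is understated.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class LODEstimate:
    """Pseudo-univariate LOD with its regression ingredients.

    slope/intercept describe the predicted-vs-nominal line; ``s_res`` is
    the residual SD (M, n-2 denominator); ``lod`` is in M. ``valid`` is
    False when the slope is non-positive (no usable calibration).
    """

    slope: float
    intercept: float
    s_res: float
    multiplier: float
    lod: float
    n: int
    valid: bool = True


def lod_from_predictions(
    c_nominal: np.ndarray,
    c_predicted: np.ndarray,
    multiplier: float = 3.3,
) -> LODEstimate:
    """Estimate the LOD from (nominal, cross-validated predicted) pairs."""
    c = np.asarray(c_nominal, dtype=float).ravel()
    p = np.asarray(c_predicted, dtype=float).ravel()
    if c.size != p.size:
        raise ValueError("nominal and predicted vectors must have equal length")
    if c.size < 3:
        raise ValueError("need at least 3 points for a residual SD (n-2 dof)")
    if np.ptp(c) == 0:
        raise ValueError("nominal concentrations are all equal; no calibration line")
    if multiplier <= 0:
        raise ValueError("multiplier must be > 0")

    b, a = np.polyfit(c, p, 1)
    resid = p - (a + b * c)
    s_res = float(np.sqrt(np.sum(resid**2) / (c.size - 2)))
    if b <= 0:
        warnings.warn(
            f"predicted-vs-nominal slope {b:.3g} is not positive; "
            "LOD estimate flagged invalid",
            RuntimeWarning,
            stacklevel=2,
        )
        return LODEstimate(
            slope=float(b),
            intercept=float(a),
            s_res=s_res,
            multiplier=multiplier,
            lod=float("nan"),
            n=c.size,
            valid=False,
        )
    return LODEstimate(
        slope=float(b),
        intercept=float(a),
        s_res=s_res,
        multiplier=multiplier,
        lod=multiplier * s_res / float(b),
        n=c.size,
        valid=True,
    )
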