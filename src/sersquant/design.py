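"""Latin hypercube mixture designs for multiplexed calibration experiments.

An exhaustive factorial over four dyes at 21 concentration levels each would
require 21**4 = 194,481 mixtures; a Latin hypercube sample (LHS) covers the
same concentration space with a small number of rows by placing exactly one
point in each of m equal-probability strata of every factor.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

#: Upper bound of the linear range established for each dye (molar).
#: Sudan I 0.048 mM, II 0.036 mM, III 0.028 mM, IV 0.026 mM.
SUDAN_LINEAR_RANGE_M: dict[str, float] = {
    "sudan_i": 4.8e-5,
    "sudan_ii": 3.6e-5,
    "sudan_iii": 2.8e-5,
    "sudan_iv": 2.6e-5,
}


@dataclass
class DesignTable:
    """m x p table of mixture compositions.

    ``unit`` is ``"fraction"`` (fraction of each analyte's linear range, in
    [0, 1]) or ``"molar"`` (absolute concentration in M). ``ranges`` maps
    column name to the linear-range upper bound used for molar scaling;
    ``n_levels`` records the snap grid if the design was discretised.
    """

    table: pd.DataFrame
    unit: str = "fraction"
    ranges: dict[str, float] = field(default_factory=dict)
    n_levels: int | None = None

    def __post_init__(self) -> None:
        if self.unit not in ("fraction", "molar"):
            raise ValueError(f"unit must be 'fraction' or 'molar', got {self.unit!r}")
        if self.table.columns.duplicated().any():
            raise ValueError("design column names must be unique")
        values = self.table.to_numpy(dtype=float)
        if self.unit == "fraction" and (values.min() < 0 or values.max() > 1):
            raise ValueError("fractional design values must lie in [0, 1]")
        if values.min() < 0:
            raise ValueError("concentrations must be non-negative")

    @property
    def analytes(self) -> list[str]:
        return list(self.table.columns)

    @property
    def m(self) -> int:
        return len(self.table)


def exhaustive_count(levels: int, factors: int) -> int:
    """Number of mixtures in a full factorial: ``levels ** factors``.

    ``exhaustive_count(21, 4)`` is the 194,481 figure that motivates LHS.
    """
    if levels < 1 or factors < 1:
        raise ValueError("levels and factors must both be >= 1")
    return int(levels) ** int(factors)


def lhs_design(
    m: int,
    p: int,
    seed: int | None = None,
    columns: Sequence[str] | None = None,
) -> DesignTable:
    """Draw an m-row, p-factor Latin hypercube sample of [0, 1]^p.

    Each column partitions [0, 1] into m equal strata, draws one uniform
    point per stratum and permutes the stratum order; columns are permuted
    independently. Fully determined by ``seed``.
    """
    if m < 1 or p < 1:
        raise ValueError("m and p must both be >= 1")
    if columns is None:
        columns = [f"x{j + 1}" for j in range(p)]
    elif len(columns) != p:
        raise ValueError(f"got {len(columns)} column names for p={p}")
    rng = np.random.default_rng(seed)
    cols = np.empty((m, p))
    for j in range(p):
        cols[:, j] = (rng.permutation(m) + rng.uniform(size=m)) / m
    return DesignTable(pd.DataFrame(cols, columns=list(columns)), unit="fraction")


def snap_to_levels(design: DesignTable, n_levels: int) -> DesignTable:
    """Round every fraction to the nearest point of an equispaced grid.

    With 21 levels the grid step is 5% of the range; ties round up. Never
    moves a point by more than half a grid step and is idempotent.
    """
    if n_levels < 2:
        raise ValueError("n_levels must be >= 2")
    if design.unit != "fraction":
        raise ValueError("snap_to_levels expects a fractional design")
    step = 1.0 / (n_levels - 1)
    # floor(x/step + 0.5) rounds ties (x exactly between grid points) up
    snapped = np.floor(design.table.to_numpy() / step + 0.5) * step
    snapped = np.clip(snapped, 0.0, 1.0)
    return DesignTable(
        pd.DataFrame(snapped, columns=design.table.columns, index=design.table.index),
        unit="fraction",
        ranges=dict(design.ranges),
        n_levels=n_levels,
    )


def scale_design(design: DesignTable, ranges: Mapping[str, float]) -> DesignTable:
    """Convert a fractional design to molar concentrations.

    A fraction f of analyte a maps to ``f * ranges[a]``: 0% means the dye is
    absent, 100% means the upper bound of its linear range.
    """
    if design.unit != "fraction":
        raise ValueError("scale_design expects a fractional design")
    missing = [c for c in design.table.columns if c not in ranges]
    if missing:
        raise ValueError(f"no concentration range given for column(s): {missing}")
    scaled = design.table.copy()
    for col in scaled.columns:
        if ranges[col] <= 0:
            raise ValueError(f"range for {col!r} must be positive")
        scaled[col] = scaled[col] * float(ranges[col])
    return DesignTable(
        scaled,
        unit="molar",
        ranges={c: float(ranges[c]) for c in scaled.columns},
        n_levels=design.n_levels,
    )


def sudan_mixture_design(
    m: int = 90,
    n_levels: int | None = 21,
    seed: int | None = None,
) -> DesignTable:
    """Convenience: m-mixture LHS over the four Sudan dyes in molar units."""
    names = list(SUDAN_LINEAR_RANGE_M)
    design = lhs_design(m, len(names), seed=seed, columns=names)
    if n_levels is not None:
        design = snap_to_levels(design, n_levels)
    return scale_design(design, SUDAN_LINEAR_RANGE_M)
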