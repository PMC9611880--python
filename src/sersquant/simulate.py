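"""Synthetic SERS spectrum generator.

Emulates colloidal-gold SERS measurements of azo dyes: each spectrum is a
sum of dye component signatures scaled by a concentration response, a fixed
matrix background (aggregated colloid, citrate capping agent and
acetonitrile solvent), a smooth random baseline drift, and noise. The
concentration response is Langmuir-like, r(c) = c / (1 + c / c_sat),
reducing to the linear r(c) = c when the saturation constant is infinite —
the finite-c_sat mode emulates adsorption competition on the nanoparticle
surface.

Ground-truth concentrations travel in the metadata, so every downstream
stage (preprocessing, PCA, PLS calibration, validation, LOD) is testable
without access to the original instrument data.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .design import DesignTable

logger = logging.getLogger(__name__)

#: Seven-level dilution series used for the single-dye (simplex) studies,
#: 0.03 mM down to 0.002 mM, in molar units.
SUDAN_DILUTION_LEVELS_M = np.array([3.0e-5, 2.5e-5, 2.0e-5, 1.5e-5, 1.0e-5, 5.0e-6, 2.0e-6])


@dataclass(frozen=True)
class PeakModel:
    """One vibrational band: center (cm-1), HWHM width (cm-1), relative
    height, and line shape ("lorentzian" or "gaussian")."""

    center: float
    width: float
    height: float
    shape: str = "lorentzian"

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise ValueError("peak width must be > 0")
        if self.height < 0:
            raise ValueError("peak height must be >= 0")
        if self.shape not in ("lorentzian", "gaussian"):
            raise ValueError(f"unknown line shape {self.shape!r}")

    def evaluate(self, axis: np.ndarray) -> np.ndarray:
        d = axis - self.center
        if self.shape == "lorentzian":
            return self.height * self.width**2 / (d**2 + self.width**2)
        sigma = self.width / math.sqrt(2.0 * math.log(2.0))
        return self.height * np.exp(-(d**2) / (2.0 * sigma**2))


@dataclass
class ComponentLibrary:
    """Per-analyte peak sets, response gains and the matrix background.

    ``gains`` are intensities per M of analyte; ``c_sat`` are Langmuir
    saturation constants in M (``inf`` for a linear response).
    """

    analyte_peaks: dict[str, list[PeakModel]]
    matrix_peaks: list[PeakModel] = field(default_factory=list)
    gains: dict[str, float] = field(default_factory=dict)
    c_sat: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in self.analyte_peaks:
            self.gains.setdefault(name, 1.0)
            self.c_sat.setdefault(name, math.inf)
        for name, g in self.gains.items():
            if g <= 0:
                raise ValueError(f"gain for {name!r} must be > 0")
        for name, cs in self.c_sat.items():
            if cs <= 0:
                raise ValueError(f"c_sat for {name!r} must be > 0 (or inf)")

    @property
    def analytes(self) -> list[str]:
        return list(self.analyte_peaks)

    def response(self, name: str, c: float) -> float:
        """Langmuir-type response r(c) = c / (1 + c/c_sat)."""
        cs = self.c_sat[name]
        return c if math.isinf(cs) else c / (1.0 + c / cs)


@dataclass(frozen=True)
class SimulationConfig:
    """Acquisition and noise settings.

    Axis defaults cover 400-2000 cm-1 at 2 cm-1 spacing (801 channels).
    ``additive_noise_sd`` is per channel in intensity units (component
    apexes are O(1)); ``multiplicative_noise_sd`` is the fractional
    spectrum-level intensity variability between replicates;
    ``drift_amplitude`` scales a smooth random cubic baseline.
    """

    axis_start: float = 400.0
    axis_stop: float = 2000.0
    axis_step: float = 2.0
    additive_noise_sd: float = 0.01
    multiplicative_noise_sd: float = 0.02
    drift_amplitude: float = 0.05
    replicates: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.axis_start >= self.axis_stop:
            raise ValueError("axis_start must be < axis_stop")
        if self.axis_step <= 0:
            raise ValueError("axis_step must be > 0")
        if self.additive_noise_sd < 0 or self.multiplicative_noise_sd < 0:
            raise ValueError("noise SDs must be >= 0")
        if self.drift_amplitude < 0:
            raise ValueError("drift_amplitude must be >= 0")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")

    def axis(self) -> np.ndarray:
        n = int(round((self.axis_stop - self.axis_start) / self.axis_step)) + 1
        return self.axis_start + self.axis_step * np.arange(n)


@dataclass
class SpectraSet:
    """A stack of spectra on a shared Raman-shift axis plus metadata.

    ``metadata`` has one row per spectrum: sample_id, replicate and one
    ``conc_<analyte>_M`` column per analyte.
    """

    axis: np.ndarray
    intensities: np.ndarray
    metadata: pd.DataFrame

    def __post_init__(self) -> None:
        self.axis = np.asarray(self.axis, dtype=float)
        self.intensities = np.atleast_2d(np.asarray(self.intensities, dtype=float))
        if np.any(np.diff(self.axis) <= 0):
            raise ValueError("axis must be strictly increasing")
        if self.intensities.shape[1] != self.axis.size:
            raise ValueError(
                f"{self.intensities.shape[1]} channels vs axis of {self.axis.size}"
            )
        if len(self.metadata) != self.intensities.shape[0]:
            raise ValueError(
                f"metadata has {len(self.metadata)} rows for "
                f"{self.intensities.shape[0]} spectra"
            )
        conc = self.metadata[self.conc_columns].to_numpy(dtype=float)
        if conc.size and conc.min() < 0:
            raise ValueError("concentrations must be >= 0")

    @property
    def n_spectra(self) -> int:
        return self.intensities.shape[0]

    @property
    def conc_columns(self) -> list[str]:
        return [c for c in self.metadata.columns if c.startswith("conc_")]

    @property
    def analytes(self) -> list[str]:
        return [c[len("conc_") : -len("_M")] for c in self.conc_columns]

    def concentrations(self) -> pd.DataFrame:
        """Per-spectrum analyte concentrations (M), columns named by analyte."""
        out = self.metadata[self.conc_columns].astype(float).copy()
        out.columns = self.analytes
        return out

    @property
    def sample_ids(self) -> np.ndarray:
        return self.metadata["sample_id"].to_numpy()


def build_component_spectrum(
    peaks: Sequence[PeakModel], axis: np.ndarray
) -> np.ndarray:
    """Sum the line shapes of ``peaks`` over ``axis``.

    An empty peak list yields a zero vector. A peak centered outside the
    axis is logged at warning level but still evaluated — its tails may
    contribute.
    """
    axis = np.asarray(axis, dtype=float)
    if np.any(np.diff(axis) <= 0):
        raise ValueError("axis must be strictly increasing")
    out = np.zeros_like(axis)
    for peak in peaks:
        if not axis[0] <= peak.center <= axis[-1]:
            logger.warning(
                "peak center %.1f cm-1 lies outside the axis [%.1f, %.1f]",
                peak.center,
                axis[0],
                axis[-1],
            )
        out += peak.evaluate(axis)
    return out


def default_library() -> ComponentLibrary:
    """Built-in four-dye library plus colloid/citrate/solvent background.

    The Sudan I band positions (722, 753, 1000, 1198, 1258, 1506 cm-1) are
    the ones reported for that dye; the Sudan II-IV and matrix peak sets are
    synthetic defaults, chosen to be mutually distinguishable with partial
    overlap — they are plumbing, not literature assignments. Gains place the
    strongest dye band at roughly half the matrix apex at the top of each
    dye's linear range; matrix bands are broad so the background dominates
    each spectrum's overall variance, as it does in colloidal SERS of dilute
    analytes.
    """

    def peaks(spec: list[tuple[float, float, float]]) -> list[PeakModel]:
        return [PeakModel(center=c, width=w, height=h) for c, w, h in spec]

    analyte_peaks = {
        "sudan_i": peaks(
            [
                (722.0, 6.0, 0.90),
                (753.0, 6.0, 1.00),
                (1000.0, 5.0, 0.80),
                (1198.0, 7.0, 0.70),
                (1258.0, 7.0, 0.75),
                (1506.0, 8.0, 0.85),
            ]
        ),
        # synthetic band sets for Sudan II-IV (distinguishable, partial overlap)
        "sudan_ii": peaks(
            [
                (590.0, 7.0, 0.70),
                (726.0, 6.0, 0.60),
                (988.0, 5.0, 1.00),
                (1130.0, 7.0, 0.65),
                (1390.0, 8.0, 0.80),
                (1560.0, 8.0, 0.75),
            ]
        ),
        "sudan_iii": peaks(
            [
                (640.0, 7.0, 0.65),
                (905.0, 6.0, 0.85),
                (1045.0, 6.0, 0.70),
                (1226.0, 7.0, 1.00),
                (1440.0, 8.0, 0.75),
                (1594.0, 8.0, 0.80),
            ]
        ),
        "sudan_iv": peaks(
            [
                (560.0, 7.0, 0.60),
                (835.0, 6.0, 0.80),
                (968.0, 5.0, 0.70),
                (1165.0, 7.0, 0.90),
                (1310.0, 8.0, 1.00),
                (1620.0, 8.0, 0.70),
            ]
        ),
    }
    # broad colloid/citrate/acetonitrile background bands
    matrix_peaks = peaks(
        [
            (505.0, 45.0, 0.55),
            (700.0, 35.0, 0.45),
            (920.0, 25.0, 0.90),
            (1035.0, 30.0, 0.70),
            (1380.0, 50.0, 1.00),
            (1640.0, 40.0, 0.60),
        ]
    )
    gains = {
        "sudan_i": 1.3e4,
        "sudan_ii": 1.6e4,
        "sudan_iii": 2.0e4,
        "sudan_iv": 2.2e4,
    }
    return ComponentLibrary(
        analyte_peaks=analyte_peaks, matrix_peaks=matrix_peaks, gains=gains
    )


def saturating_library(c_sat: float = 2.0e-5) -> ComponentLibrary:
    """Default library with a finite Langmuir constant on every dye.

    Emulates the adsorption-competition regime where response flattens as
    surface coverage approaches a monolayer.
    """
    lib = default_library()
    lib.c_sat = {name: c_sat for name in lib.analytes}
    return lib


def _smooth_drift(axis: np.ndarray, amplitude: float, rng: np.random.Generator) -> np.ndarray:
    """Random cubic over the axis, normalized to max |value| = 1, scaled."""
    if amplitude == 0:
        return np.zeros_like(axis)
    x = np.linspace(-1.0, 1.0, axis.size)
    coeffs = rng.normal(size=4)
    curve = np.polyval(coeffs, x)
    peak = np.abs(curve).max()
    if peak == 0:
        return np.zeros_like(axis)
    return amplitude * curve / peak


def simulate_mixtures(
    design: DesignTable,
    library: ComponentLibrary,
    config: SimulationConfig,
) -> SpectraSet:
    """Simulate ``config.replicates`` spectra per design row.

    Each spectrum is
    ``(1 + eps) * (sum_j gain_j r(c_j) P_j + matrix) + drift + noise``
    with eps a per-replicate multiplicative deviation, drift a smooth
    per-replicate baseline and noise additive Gaussian per channel. Fully
    reproducible from ``config.seed``.
    """
    if design.unit != "molar":
        raise ValueError("simulate_mixtures expects a molar design")
    unknown = [c for c in design.table.columns if c not in library.analyte_peaks]
    if unknown:
        raise ValueError(
            f"design column(s) {unknown} not in library "
            f"(available: {library.analytes})"
        )
    conc = design.table.to_numpy(dtype=float)
    if conc.min() < 0:
        raise ValueError("design contains negative concentrations")

    axis = config.axis()
    components = {
        name: build_component_spectrum(library.analyte_peaks[name], axis)
        for name in design.table.columns
    }
    matrix = build_component_spectrum(library.matrix_peaks, axis)
    rng = np.random.default_rng(config.seed)

    n_digits = max(3, len(str(design.m)))
    spectra = []
    records = []
    for i in range(design.m):
        sample_id = (
            str(design.table.index[i])
            if design.table.index.dtype == object
            else f"s{i + 1:0{n_digits}d}"
        )
        clean = matrix.copy()
        for j, name in enumerate(design.table.columns):
            clean = clean + library.gains[name] * library.response(name, conc[i, j]) * components[name]
        for r in range(config.replicates):
            eps = rng.normal(0.0, config.multiplicative_noise_sd) if config.multiplicative_noise_sd else 0.0
            drift = _smooth_drift(axis, config.drift_amplitude, rng)
            noise = (
                rng.normal(0.0, config.additive_noise_sd, size=axis.size)
                if config.additive_noise_sd
                else np.zeros_like(axis)
            )
            spectra.append((1.0 + eps) * clean + drift + noise)
            rec = {"sample_id": sample_id, "replicate": r + 1}
            for j, name in enumerate(design.table.columns):
                rec[f"conc_{name}_M"] = conc[i, j]
            records.append(rec)

    return SpectraSet(
        axis=axis,
        intensities=np.vstack(spectra),
        metadata=pd.DataFrame.from_records(records),
    )


def simulate_dilution_series(
    analyte: str,
    levels: Sequence[float],
    library: ComponentLibrary,
    config: SimulationConfig,
) -> SpectraSet:
    """Single-analyte dilution series: one sample id per concentration level.

    The default study design is seven levels (0.03 mM down to 0.002 mM)
    measured in three technical replicates.
    """
    if analyte not in library.analyte_peaks:
        raise ValueError(
            f"unknown analyte {analyte!r}; library holds {library.analytes}"
        )
    levels = np.asarray(levels, dtype=float)
    if np.any(levels <= 0):
        raise ValueError("dilution levels must be strictly positive")
    if np.unique(levels).size != levels.size:
        raise ValueError("dilution levels must be distinct")
    design = DesignTable(
        pd.DataFrame({analyte: levels}), unit="molar", ranges={analyte: float(levels.max())}
    )
    return simulate_mixtures(design, library, config)
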