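"""End-to-end driver: design -> simulate -> preprocess -> model -> validate -> LOD.

Two recipes mirror the two study designs:

* ``simplex`` — per dye, a seven-level dilution series in triplicate;
  SNV-preprocessed spectra are calibrated by PLS1 under k-fold double
  cross-validation (k = number of levels) and the pooled held-out
  predictions feed the LOD estimate. The PCA chain (AsLS -> Savitzky-Golay
  -> vector normalization) feeds an exploratory PCA whose scores are
  written alongside.
* ``quadruplex`` — a Latin-hypercube mixture design over all four dyes,
  simulated in triplicate; PLS1 per dye and one PLS2 model are validated
  by bootstrap resampling with inner component selection.

One master seed drives everything: stage seeds are drawn deterministically
from ``numpy.random.SeedSequence(master_seed)``, so re-running a config
reproduces every numeric output exactly.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .decomposition import SpectralPCA
from .design import sudan_mixture_design
from .io import (
    append_manifest,
    write_design_csv,
    write_metadata_csv,
    write_spectra_csv,
)
from .lod import lod_from_predictions
from .preprocessing import PreprocessConfig, preprocess_set
from .simulate import (
    SUDAN_DILUTION_LEVELS_M,
    SimulationConfig,
    default_library,
    simulate_dilution_series,
    simulate_mixtures,
)
from .validation import BootstrapConfig, CVConfig, bootstrap_validate, double_cv

logger = logging.getLogger(__name__)


def stage_seeds(master_seed: int, n: int = 16) -> list[int]:
    """Deterministic per-stage seeds derived from one master seed."""
    return [int(s) for s in np.random.SeedSequence(master_seed).generate_state(n) % (2**31)]


def run_simplex(
    out_dir: str | Path,
    seed: int = 0,
    levels: np.ndarray | None = None,
    additive_noise_sd: float = 0.01,
    multiplicative_noise_sd: float = 0.02,
    drift_amplitude: float = 0.05,
    replicates: int = 3,
    k: int | None = None,
    a_max: int = 10,
    lod_multiplier: float = 3.3,
    analytes: list[str] | None = None,
) -> dict:
    """Dilution-series workflow for each dye; returns summary tables."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    levels = SUDAN_DILUTION_LEVELS_M if levels is None else np.asarray(levels, float)
    library = default_library()
    analytes = analytes or library.analytes
    seeds = stage_seeds(seed, 4 * len(analytes))
    k = k or levels.size

    summary_rows = []
    pred_frames = []
    for i, dye in enumerate(analytes):
        sim = SimulationConfig(
            additive_noise_sd=additive_noise_sd,
            multiplicative_noise_sd=multiplicative_noise_sd,
            drift_amplitude=drift_amplitude,
            replicates=replicates,
            seed=seeds[4 * i],
        )
        spectra = simulate_dilution_series(dye, levels, library, sim)
        write_spectra_csv(spectra, out_dir / f"spectra_{dye}.csv")
        write_metadata_csv(spectra, out_dir / f"metadata_{dye}.csv")

        snv_set = preprocess_set(spectra, PreprocessConfig(chain="snv_chain"))
        y = snv_set.concentrations()[dye].to_numpy()
        cv = double_cv(
            snv_set.intensities,
            y,
            snv_set.sample_ids,
            CVConfig(k=k, a_max=a_max),
            seed=seeds[4 * i + 1],
            response=dye,
        )
        # held-out predictions per spectrum drive the LOD
        merged = pd.DataFrame(
            {"sample_id": snv_set.sample_ids, "nominal": y}
        ).merge(cv.predictions[["sample_id", "pred_mean"]], on="sample_id")
        est = lod_from_predictions(
            merged["nominal"], merged["pred_mean"], multiplier=lod_multiplier
        )
        summary_rows.append(
            {
                "analyte": dye,
                "q2": cv.stats.loc[dye, "q2_mean"],
                "rmsecv_M": cv.stats.loc[dye, "rmsecv_mean"],
                "lod_M": est.lod,
                "lod_slope": est.slope,
                "lod_s_res_M": est.s_res,
                "lod_valid": est.valid,
            }
        )
        preds = cv.predictions.copy()
        preds.insert(0, "analyte", dye)
        pred_frames.append(preds)

        # exploratory PCA branch on the baseline-corrected chain
        pca_set = preprocess_set(spectra, PreprocessConfig(chain="pca_chain"))
        pca = SpectralPCA(n_components=2).fit(pca_set.intensities)
        scores = pd.DataFrame(pca.scores_, columns=["pc1", "pc2"])
        scores.insert(0, "sample_id", pca_set.sample_ids)
        scores["conc_M"] = y
        scores.to_csv(out_dir / f"pca_scores_{dye}.csv", index=False)

    summary = pd.DataFrame(summary_rows)
    summary.to_csv(out_dir / "simplex_summary.csv", index=False)
    predictions = pd.concat(pred_frames, ignore_index=True)
    predictions.to_csv(out_dir / "simplex_predictions.csv", index=False)
    append_manifest(
        out_dir,
        "run_simplex",
        {
            "seed": seed,
            "levels_M": list(map(float, levels)),
            "additive_noise_sd": additive_noise_sd,
            "multiplicative_noise_sd": multiplicative_noise_sd,
            "drift_amplitude": drift_amplitude,
            "replicates": replicates,
            "k": k,
            "a_max": a_max,
            "lod_multiplier": lod_multiplier,
        },
        files={"summary": out_dir / "simplex_summary.csv"},
    )
    return {"summary": summary, "predictions": predictions}


def run_quadruplex(
    out_dir: str | Path,
    seed: int = 0,
    m: int = 90,
    n_levels: int | None = 21,
    replicates: int = 3,
    additive_noise_sd: float = 0.01,
    multiplicative_noise_sd: float = 0.02,
    drift_amplitude: float = 0.05,
    n_boot_pls1: int = 1000,
    n_boot_pls2: int = 10000,
    a_max: int = 10,
) -> dict:
    """LHS mixture workflow: PLS1 per dye + one PLS2, bootstrap-validated."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    seeds = stage_seeds(seed, 8)
    design = sudan_mixture_design(m=m, n_levels=n_levels, seed=seeds[0])
    write_design_csv(design, out_dir / "design.csv")

    library = default_library()
    sim = SimulationConfig(
        additive_noise_sd=additive_noise_sd,
        multiplicative_noise_sd=multiplicative_noise_sd,
        drift_amplitude=drift_amplitude,
        replicates=replicates,
        seed=seeds[1],
    )
    spectra = simulate_mixtures(design, library, sim)
    write_spectra_csv(spectra, out_dir / "spectra_quadruplex.csv")
    write_metadata_csv(spectra, out_dir / "metadata_quadruplex.csv")

    snv_set = preprocess_set(spectra, PreprocessConfig(chain="snv_chain"))
    conc = snv_set.concentrations()
    dyes = list(conc.columns)

    stats_frames = []
    for i, dye in enumerate(dyes):
        summary = bootstrap_validate(
            snv_set.intensities,
            conc[dye].to_numpy(),
            snv_set.sample_ids,
            mode="pls1",
            config=BootstrapConfig(n_boot=n_boot_pls1, seed=seeds[2 + i], a_max=a_max),
            responses=[dye],
        )
        s = summary.stats.copy()
        s.insert(0, "model", "pls1")
        stats_frames.append(s)
        summary.predictions.to_csv(
            out_dir / f"bootstrap_pls1_predictions_{dye}.csv", index=False
        )

    pls2 = bootstrap_validate(
        snv_set.intensities,
        conc.to_numpy(),
        snv_set.sample_ids,
        mode="pls2",
        config=BootstrapConfig(n_boot=n_boot_pls2, seed=seeds[6], a_max=a_max),
        responses=dyes,
    )
    s2 = pls2.stats.copy()
    s2.insert(0, "model", "pls2")
    stats_frames.append(s2)
    pls2.predictions.to_csv(out_dir / "bootstrap_pls2_predictions.csv", index=False)

    stats = pd.concat(stats_frames).reset_index()
    stats.to_csv(out_dir / "quadruplex_summary.csv", index=False)
    append_manifest(
        out_dir,
        "run_quadruplex",
        {
            "seed": seed,
            "m": m,
            "n_levels": n_levels,
            "replicates": replicates,
            "additive_noise_sd": additive_noise_sd,
            "multiplicative_noise_sd": multiplicative_noise_sd,
            "drift_amplitude": drift_amplitude,
            "n_boot_pls1": n_boot_pls1,
            "n_boot_pls2": n_boot_pls2,
            "a_max": a_max,
        },
        files={"summary": out_dir / "quadruplex_summary.csv"},
    )
    return {"summary": stats, "design": design}


def run_pipeline(config: dict, out_dir: str | Path | None = None) -> dict:
    """Execute a recipe described by a configuration mapping.

    ``config`` must name a ``recipe`` (``simplex`` or ``quadruplex``), a
    ``seed`` and an ``out_dir`` (overridable by the argument); remaining
    keys are forwarded to the recipe runner.
    """
    cfg = dict(config)
    recipe = cfg.pop("recipe", None)
    if recipe not in ("simplex", "quadruplex"):
        raise ValueError(f"config must set recipe to 'simplex' or 'quadruplex', got {recipe!r}")
    out = Path(out_dir or cfg.pop("out_dir", None) or f"results_{recipe}")
    cfg.pop("out_dir", None)
    seed = int(cfg.pop("seed", 0))
    runner = run_simplex if recipe == "simplex" else run_quadruplex
    try:
        return runner(out, seed=seed, **cfg)
    except TypeError as exc:
        raise ValueError(f"invalid {recipe} configuration: {exc}") from exc
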