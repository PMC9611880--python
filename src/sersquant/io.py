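"""CSV readers/writers and run manifests.

Spectra travel as a wide CSV — first column ``wavenumber_cm-1``, one column
per spectrum — alongside a metadata CSV (sample_id, replicate, one
``conc_<analyte>_M`` column per analyte). Numbers are written as decimal
text with 17 significant digits so a write/read round trip reproduces every
float bit-exactly.
"""

from __future__ import annotations

import hashlib
import json
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .simulate import SpectraSet

AXIS_COLUMN = "wavenumber_cm-1"


def write_spectra_csv(spectra: SpectraSet, path: str | Path) -> None:
    """Write the wide spectra CSV (one column per spectrum)."""
    path = Path(path)
    names = [
        f"{sid}_r{rep}"
        for sid, rep in zip(
            spectra.metadata["sample_id"], spectra.metadata["replicate"]
        )
    ]
    df = pd.DataFrame(spectra.intensities.T, columns=names)
    df.insert(0, AXIS_COLUMN, spectra.axis)
    df.to_csv(path, index=False, float_format="%.17g", lineterminator="\n")


def write_metadata_csv(spectra: SpectraSet, path: str | Path) -> None:
    spectra.metadata.to_csv(
        Path(path), index=False, float_format="%.17g", lineterminator="\n"
    )


def read_spectra_csv(
    spectra_path: str | Path, metadata_path: str | Path
) -> SpectraSet:
    """Read the spectra + metadata CSV pair back into a SpectraSet."""
    spectra_path, metadata_path = Path(spectra_path), Path(metadata_path)
    df = pd.read_csv(spectra_path, float_precision="round_trip")
    if df.columns[0] != AXIS_COLUMN:
        raise ValueError(
            f"{spectra_path}: first column must be {AXIS_COLUMN!r}, "
            f"got {df.columns[0]!r}"
        )
    for col in df.columns:
        bad = df[col].isna() | ~np.isfinite(pd.to_numeric(df[col], errors="coerce"))
        if bad.any():
            row = int(np.flatnonzero(bad)[0])
            raise ValueError(
                f"{spectra_path}: non-numeric or missing value at row {row + 2}, "
                f"column {col!r}"
            )
    axis = df[AXIS_COLUMN].to_numpy(dtype=float)
    if np.any(np.diff(axis) <= 0):
        raise ValueError(f"{spectra_path}: wavenumber axis is not strictly increasing")
    intensities = df.drop(columns=AXIS_COLUMN).to_numpy(dtype=float).T

    meta = pd.read_csv(metadata_path, float_precision="round_trip")
    required = {"sample_id", "replicate"}
    if not required <= set(meta.columns):
        raise ValueError(
            f"{metadata_path}: missing required column(s) "
            f"{sorted(required - set(meta.columns))}"
        )
    if len(meta) != intensities.shape[0]:
        raise ValueError(
            f"metadata has {len(meta)} rows but spectra file holds "
            f"{intensities.shape[0]} spectra"
        )
    return SpectraSet(axis=axis, intensities=intensities, metadata=meta)


def write_design_csv(design, path: str | Path) -> None:
    df = design.table.copy()
    df.insert(0, "sample", [f"s{i + 1:03d}" for i in range(len(df))])
    df.to_csv(Path(path), index=False, float_format="%.17g", lineterminator="\n")


def read_design_csv(path: str | Path, unit: str = "molar"):
    from .design import DesignTable

    df = pd.read_csv(Path(path), float_precision="round_trip")
    if "sample" in df.columns:
        df = df.drop(columns="sample")
    return DesignTable(df, unit=unit)


def read_config(path: str | Path) -> dict:
    """Load a plain-text key-value (YAML) configuration file."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: expected a mapping at the top level")
    return cfg


def _digest(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def append_manifest(
    out_dir: str | Path,
    command: str,
    params: dict,
    files: dict[str, str | Path] | None = None,
) -> Path:
    """Append one run record to ``manifest.jsonl`` in the output directory.

    Records the command, full parameter set, timestamp, package version and
    a sha256 digest of each input/output file. Append-only by construction.
    """
    from . import __version__

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    record = {
        "command": command,
        "params": params,
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S%z"),
        "version": __version__,
        "files": {
            role: {"path": str(p), "sha256": _digest(Path(p))}
            for role, p in (files or {}).items()
            if Path(p).exists()
        },
    }
    manifest = out_dir / "manifest.jsonl"
    with open(manifest, "a") as fh:
        fh.write(json.dumps(record, default=str) + "\n")
    return manifest
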