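"""CSV / manifest ingestion and report writing.

File conventions:

* quenching CSV — columns ``conc_M, intensity``; the ``conc_M == 0`` row
  defines F0 for that temperature;
* spectrum CSV — columns ``wavelength_nm, intensity`` (or
  ``wavelength_nm, ellipticity`` for CD);
* standards CSV — columns ``conc_ug_ml, absorbance``;
* manifest — YAML or JSON mapping temperatures to quenching CSV paths,
  plus ``tau0_s`` and ``diffusion_limit`` overrides.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .exceptions import InvalidInputError
from .quenching import (
    DEFAULT_TAU0,
    DIFFUSION_LIMIT,
    QuenchingBindingModel,
    QuenchingSeries,
)
from .spectra import Spectrum

__all__ = [
    "read_quenching_csv",
    "read_spectrum_csv",
    "read_standards_csv",
    "load_manifest",
    "model_from_manifest",
    "write_report_json",
    "write_constants_csv",
]


def read_quenching_csv(path, temperature: float) -> QuenchingSeries:
    """One temperature's titration from a ``conc_M, intensity`` CSV."""
    df = pd.read_csv(path)
    if not {"conc_M", "intensity"}.issubset(df.columns):
        raise InvalidInputError(f"{path}: need columns conc_M, intensity")
    df = df.sort_values("conc_M")
    zero = df[df["conc_M"] == 0.0]
    if len(zero) != 1:
        raise InvalidInputError(f"{path}: exactly one conc_M == 0 row must define F0")
    rest = df[df["conc_M"] > 0.0]
    return QuenchingSeries(
        temperature=temperature,
        concentrations=rest["conc_M"].to_numpy(),
        f0=float(zero["intensity"].iloc[0]),
        f=rest["intensity"].to_numpy(),
    )


def read_spectrum_csv(path, kind: str = "emission", label: str = "") -> Spectrum:
    df = pd.read_csv(path)
    ycol = "intensity" if "intensity" in df.columns else "ellipticity"
    if "wavelength_nm" not in df.columns or ycol not in df.columns:
        raise InvalidInputError(
            f"{path}: need columns wavelength_nm and intensity/ellipticity"
        )
    df = df.sort_values("wavelength_nm")
    return Spectrum(
        wavelengths=df["wavelength_nm"].to_numpy(),
        intensities=df[ycol].to_numpy(),
        kind=kind,
        label=label or Path(path).stem,
    )


def read_standards_csv(path) -> list[tuple[float, float]]:
    df = pd.read_csv(path)
    if not {"conc_ug_ml", "absorbance"}.issubset(df.columns):
        raise InvalidInputError(f"{path}: need columns conc_ug_ml, absorbance")
    return list(zip(df["conc_ug_ml"].astype(float), df["absorbance"].astype(float)))


def load_manifest(path) -> dict:
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        return json.loads(text)
    return yaml.safe_load(text)


def model_from_manifest(path) -> QuenchingBindingModel:
    """Build a :class:`QuenchingBindingModel` from a manifest.

    Expected layout::

        tau0_s: 1.0e-8            # optional
        diffusion_limit: 2.0e10   # optional
        anchored: false           # optional
        series:
          - {temperature_K: 293, file: q293.csv}
          - {temperature_K: 303, file: q303.csv}
    """
    manifest = load_manifest(path)
    base = Path(path).parent
    entries = manifest.get("series")
    if not entries:
        raise InvalidInputError(f"{path}: manifest must list 'series'")
    series = [
        read_quenching_csv(base / e["file"], float(e["temperature_K"]))
        for e in entries
    ]
    return QuenchingBindingModel(
        series,
        tau0=float(manifest.get("tau0_s", DEFAULT_TAU0)),
        diffusion_limit=float(manifest.get("diffusion_limit", DIFFUSION_LIMIT)),
        anchored=bool(manifest.get("anchored", False)),
    )


def write_report_json(results, path) -> None:
    Path(path).write_text(json.dumps(results.to_report(), indent=2) + "\n")


def write_constants_csv(results, path) -> None:
    results.to_frame().to_csv(path)
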