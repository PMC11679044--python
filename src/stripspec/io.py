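"""Text-format readers and writers for spectra, scans and calibration models.

On-disk conventions (all plain text):

* spectrum — two numeric columns (wavelength nm, intensity counts);
  ``#`` starts a comment line; comma or whitespace delimited.
* strip-scan manifest — YAML naming the three spectrum files plus metadata.
* calibration model — JSON with a ``schema`` version tag.

Readers never alter numeric values beyond sorting rows by wavelength.
"""

from __future__ import annotations

import json
import math
import os
from pathlib import Path

import numpy as np
import yaml

from .errors import (
    InsufficientDataError,
    SchemaVersionError,
    SpectrumParseError,
    SpectrumValidationError,
)
from .models import CalibrationModel, LodResult, Spectrum, StripScan

CALIBRATION_SCHEMA = "stripspec.calibration-model/v1"


def read_spectrum(path: str | os.PathLike, region_label: str) -> Spectrum:
    """Read a two-column spectrum file into a :class:`Spectrum`.

    Rows are sorted by wavelength if the file is unordered. Duplicate
    wavelengths, malformed rows and negative intensities are rejected.
    """
    wavelengths: list[float] = []
    intensities: list[float] = []
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            fields = line.replace(",", " ").split()
            if len(fields) != 2:
                raise SpectrumParseError(
                    f"{path}:{lineno}: expected 2 numeric columns, "
                    f"got {len(fields)}: {raw.rstrip()!r}",
                    line_number=lineno,
                )
            try:
                wl, inten = float(fields[0]), float(fields[1])
            except ValueError as exc:
                raise SpectrumParseError(
                    f"{path}:{lineno}: non-numeric value in {raw.rstrip()!r}",
                    line_number=lineno,
                ) from exc
            if not (math.isfinite(wl) and math.isfinite(inten)):
                raise SpectrumParseError(
                    f"{path}:{lineno}: non-finite value", line_number=lineno
                )
            wavelengths.append(wl)
            intensities.append(inten)

    if len(wavelengths) < 2:
        raise InsufficientDataError(
            f"{path}: a spectrum needs at least 2 data rows, "
            f"got {len(wavelengths)}"
        )
    wl_arr = np.asarray(wavelengths)
    in_arr = np.asarray(intensities)
    order = np.argsort(wl_arr, kind="stable")
    wl_arr, in_arr = wl_arr[order], in_arr[order]
    dup = np.flatnonzero(np.diff(wl_arr) == 0)
    if dup.size:
        raise SpectrumValidationError(
            f"{path}: duplicate wavelength(s) {wl_arr[dup][:5].tolist()}"
        )
    return Spectrum(wl_arr, in_arr, region_label)


def write_spectrum(spectrum: Spectrum, path: str | os.PathLike) -> None:
    """Write a spectrum as two whitespace-delimited columns."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# region: {spectrum.region_label}\n")
        fh.write("# wavelength_nm intensity\n")
        for wl, inten in zip(spectrum.wavelengths_nm, spectrum.intensities):
            fh.write(f"{float(wl)!r} {float(inten)!r}\n")


def read_strip_scan(manifest: str | os.PathLike) -> StripScan:
    """Read a YAML strip-scan manifest and its three spectrum files.

    Spectrum paths are resolved relative to the manifest's directory.
    The common-grid invariant is enforced by :class:`StripScan`; grids
    that differ raise a grid-mismatch error (no silent resampling).
    """
    manifest = Path(manifest)
    with open(manifest, "r", encoding="utf-8") as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict):
        raise SpectrumValidationError(f"{manifest}: manifest is not a mapping")
    missing = [k for k in ("c_line", "t_line", "white") if k not in doc]
    if missing:
        raise SpectrumValidationError(
            f"{manifest}: manifest missing region entries {missing}"
        )
    base = manifest.parent

    def _load(key: str, label: str) -> Spectrum:
        p = Path(doc[key])
        return read_spectrum(p if p.is_absolute() else base / p, label)

    nominal = doc.get("nominal_concentration_ppb")
    return StripScan(
        c_line=_load("c_line", "C"),
        t_line=_load("t_line", "T"),
        white=_load("white", "W"),
        strip_id=str(doc.get("strip_id", manifest.stem)),
        nominal_concentration_ppb=None if nominal is None else float(nominal),
        timestamp=doc.get("timestamp"),
    )


def write_strip_scan(
    scan: StripScan, directory: str | os.PathLike, stem: str | None = None
) -> Path:
    """Write a scan's three spectra plus manifest into *directory*.

    Returns the manifest path.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    stem = stem or (scan.strip_id or "scan")
    names = {}
    for key, spec in (
        ("c_line", scan.c_line),
        ("t_line", scan.t_line),
        ("white", scan.white),
    ):
        fname = f"{stem}_{key}.txt"
        write_spectrum(spec, directory / fname)
        names[key] = fname
    doc = {
        **names,
        "strip_id": scan.strip_id,
        "nominal_concentration_ppb": scan.nominal_concentration_ppb,
        "timestamp": scan.timestamp,
    }
    manifest = directory / f"{stem}.manifest.yaml"
    with open(manifest, "w", encoding="utf-8") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)
    return manifest


def _model_to_dict(model: CalibrationModel) -> dict:
    doc = {
        "schema": CALIBRATION_SCHEMA,
        "y0": model.y0,
        "plateau": model.plateau,
        "k": model.k,
        "x_definition": model.x_definition,
        "fit_r2": model.fit_r2,
        "n_points": model.n_points,
        "concentration_range_ppb": list(model.concentration_range_ppb),
    }
    if model.lod is not None:
        doc["lod"] = {
            "blank_mean_ppb": model.lod.blank_mean_ppb,
            "blank_sd_ppb": model.lod.blank_sd_ppb,
            "lob_ppb": model.lod.lob_ppb,
            "lod_ppb": model.lod.lod_ppb,
            "n_blanks": model.lod.n_blanks,
        }
    return doc


def write_calibration_model(
    model: CalibrationModel, path: str | os.PathLike
) -> None:
    """Persist a calibration model as schema-tagged JSON.

    Floats are stored with ``repr`` round-trip fidelity, so
    ``read(write(m)) == m`` to full precision.
    """
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(_model_to_dict(model), fh, indent=2)
        fh.write("\n")


def read_calibration_model(path: str | os.PathLike) -> CalibrationModel:
    """Load a calibration model persisted by :func:`write_calibration_model`."""
    try:
        with open(path, "r", encoding="utf-8") as fh:
            doc = json.load(fh)
    except json.JSONDecodeError as exc:
        raise SpectrumValidationError(
            f"{path}: not valid calibration-model JSON ({exc})"
        ) from exc
    if not isinstance(doc, dict) or "schema" not in doc:
        raise SpectrumValidationError(f"{path}: missing schema tag")
    if doc["schema"] != CALIBRATION_SCHEMA:
        raise SchemaVersionError(
            f"{path}: unsupported schema {doc['schema']!r}; "
            f"this reader supports {CALIBRATION_SCHEMA!r}"
        )
    required = (
        "y0",
        "plateau",
        "k",
        "fit_r2",
        "n_points",
        "concentration_range_ppb",
    )
    missing = [key for key in required if key not in doc]
    if missing:
        raise SpectrumValidationError(f"{path}: missing fields {missing}")
    lod = None
    if doc.get("lod") is not None:
        lod = LodResult(**doc["lod"])
    return CalibrationModel(
        y0=doc["y0"],
        plateau=doc["plateau"],
        k=doc["k"],
        fit_r2=doc["fit_r2"],
        n_points=doc["n_points"],
        concentration_range_ppb=tuple(doc["concentration_range_ppb"]),
        x_definition=doc.get("x_definition", "x = log10(concentration_ppb)"),
        lod=lod,
    )
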