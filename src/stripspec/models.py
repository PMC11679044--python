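"""Core domain objects of the strip-reader pipeline.

The data flow is::

    Spectrum (C, T, W)  →  AbsorbanceProfile  →  PeakResult (ΔA)
         →  DiffResult  →  CalibrationModel  →  ConcentrationResult

All numeric containers are numpy arrays; validation happens at construction
so downstream code can assume the invariants.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np

from .errors import (
    GridMismatchError,
    InsufficientDataError,
    SpectrumValidationError,
)

REGION_LABELS = ("C", "T", "W")


@dataclass
class Spectrum:
    """One wavelength-indexed reflectance trace from one strip region.

    Parameters
    ----------
    wavelengths_nm : array-like
        Strictly increasing wavelengths in nanometres.
    intensities : array-like
        Non-negative detector counts (arbitrary units), same length.
    region_label : {"C", "T", "W"}
        Strip region the trace was taken from: control line, test line,
        or white reference area.
    """

    wavelengths_nm: np.ndarray
    intensities: np.ndarray
    region_label: str

    def __post_init__(self):
        self.wavelengths_nm = np.asarray(self.wavelengths_nm, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.region_label not in REGION_LABELS:
            raise SpectrumValidationError(
                f"region_label must be one of {REGION_LABELS}, "
                f"got {self.region_label!r}"
            )
        if self.wavelengths_nm.ndim != 1 or self.intensities.ndim != 1:
            raise SpectrumValidationError("spectrum arrays must be 1-D")
        if len(self.wavelengths_nm) != len(self.intensities):
            raise SpectrumValidationError(
                "wavelengths and intensities differ in length: "
                f"{len(self.wavelengths_nm)} vs {len(self.intensities)}"
            )
        if len(self.wavelengths_nm) < 2:
            raise InsufficientDataError(
                "a spectrum needs at least 2 samples, got "
                f"{len(self.wavelengths_nm)}"
            )
        if not np.all(np.diff(self.wavelengths_nm) > 0):
            raise SpectrumValidationError(
                "wavelengths must be strictly increasing"
            )
        if np.any(self.intensities < 0):
            raise SpectrumValidationError("intensities must be non-negative")
        if not np.all(np.isfinite(self.wavelengths_nm)) or not np.all(
            np.isfinite(self.intensities)
        ):
            raise SpectrumValidationError("spectrum values must be finite")

    def __len__(self) -> int:
        return len(self.wavelengths_nm)

    def __eq__(self, other) -> bool:
        if not isinstance(other, Spectrum):
            return NotImplemented
        return (
            self.region_label == other.region_label
            and np.array_equal(self.wavelengths_nm, other.wavelengths_nm)
            and np.array_equal(self.intensities, other.intensities)
        )

    def with_intensities(self, intensities: np.ndarray) -> "Spectrum":
        """Copy of this spectrum on the same grid with new intensities."""
        return Spectrum(self.wavelengths_nm.copy(), intensities, self.region_label)


@dataclass
class StripScan:
    """The three spectra of one strip read plus identifying metadata.

    The control line (C), test line (T) and white reference (W) must share
    an identical wavelength grid; a mismatch indicates an acquisition fault
    and is rejected rather than resampled.
    """

    c_line: Spectrum
    t_line: Spectrum
    white: Spectrum
    strip_id: str = ""
    nominal_concentration_ppb: float | None = None
    timestamp: str | None = None

    def __post_init__(self):
        for slot, spec, label in (
            ("c_line", self.c_line, "C"),
            ("t_line", self.t_line, "T"),
            ("white", self.white, "W"),
        ):
            if spec.region_label != label:
                raise SpectrumValidationError(
                    f"{slot} spectrum carries region label "
                    f"{spec.region_label!r}, expected {label!r}"
                )
        grid = self.c_line.wavelengths_nm
        for slot, spec in (("t_line", self.t_line), ("white", self.white)):
            if not np.array_equal(spec.wavelengths_nm, grid):
                offending = np.setxor1d(spec.wavelengths_nm, grid)
                raise GridMismatchError(
                    f"{slot} wavelength grid differs from c_line grid",
                    offending_wavelengths=offending,
                )
        if (
            self.nominal_concentration_ppb is not None
            and self.nominal_concentration_ppb < 0
        ):
            raise SpectrumValidationError(
                "nominal_concentration_ppb must be non-negative"
            )


@dataclass
class CalibrationPanel:
    """A set of strip scans at known spiked concentrations.

    Every scan must carry a nominal concentration, and the panel must span
    at least two distinct nonzero levels to anchor a standard curve.
    """

    scans: list[StripScan]

    def __post_init__(self):
        for scan in self.scans:
            if scan.nominal_concentration_ppb is None:
                raise SpectrumValidationError(
                    f"scan {scan.strip_id!r} lacks a nominal concentration"
                )
        nonzero = {
            s.nominal_concentration_ppb
            for s in self.scans
            if s.nominal_concentration_ppb > 0
        }
        if len(nonzero) < 2:
            raise InsufficientDataError(
                "a calibration panel needs >= 2 distinct nonzero "
                f"concentrations, got {sorted(nonzero)}"
            )

    def replicate_counts(self) -> dict[float, int]:
        counts: dict[float, int] = {}
        for scan in self.scans:
            c = scan.nominal_concentration_ppb
            counts[c] = counts.get(c, 0) + 1
        return counts

    def concentrations(self) -> list[float]:
        return sorted(self.replicate_counts())


@dataclass
class AbsorbanceProfile:
    """Wavelength-indexed absorbance of a line region vs the white reference.

    ``valid`` marks wavelengths where the intensity ratio was positive and
    the absorbance is finite; invalid points are excluded from peak search.
    """

    wavelengths_nm: np.ndarray
    absorbance: np.ndarray
    source_region: str
    valid: np.ndarray = None

    def __post_init__(self):
        self.wavelengths_nm = np.asarray(self.wavelengths_nm, dtype=float)
        self.absorbance = np.asarray(self.absorbance, dtype=float)
        if self.source_region not in ("C", "T"):
            raise SpectrumValidationError(
                f"source_region must be 'C' or 'T', got {self.source_region!r}"
            )
        if self.valid is None:
            self.valid = np.isfinite(self.absorbance)
        self.valid = np.asarray(self.valid, dtype=bool)
        if not (
            len(self.wavelengths_nm) == len(self.absorbance) == len(self.valid)
        ):
            raise SpectrumValidationError(
                "profile arrays must share one length"
            )
        if np.any(~np.isfinite(self.absorbance[self.valid])):
            raise SpectrumValidationError(
                "absorbance must be finite at every valid wavelength"
            )


@dataclass
class PeakResult:
    """Band-maximum absorbance with its 650 nm baseline deduction."""

    peak_wavelength_nm: float
    peak_absorbance: float
    baseline_absorbance_650: float
    delta_a: float


@dataclass
class DiffResult:
    """Normalized colorimetric contrast between the test and control lines.

    Diff = 1 − ΔA_T/ΔA_C. Under competitive inhibition the test line fades
    with analyte concentration, so Diff increases with concentration.
    """

    delta_a_c: float
    delta_a_t: float
    diff: float


@dataclass
class LodResult:
    """Limit of blank / limit of detection from blank replicates.

    LOB = mean + 1.645·SD (95% one-sided limit of the blank distribution);
    LOD = mean + 3·SD.
    """

    blank_mean_ppb: float
    blank_sd_ppb: float
    lob_ppb: float
    lod_ppb: float
    n_blanks: int


@dataclass
class CalibrationModel:
    """One-phase-association standard curve on log10 concentration.

    Y(x) = y0 + (plateau − y0)·(1 − e^(−k·x)) with x = log10(conc in ppb),
    so Y(0) = y0 corresponds to 1 ppb. ``k`` is the rate constant per
    log10-ppb unit; the response must increase with concentration
    (plateau > y0, k > 0).
    """

    y0: float
    plateau: float
    k: float
    fit_r2: float
    n_points: int
    concentration_range_ppb: tuple[float, float]
    x_definition: str = "x = log10(concentration_ppb)"
    lod: LodResult | None = None

    def __post_init__(self):
        if not self.k > 0:
            raise SpectrumValidationError(f"k must be > 0, got {self.k}")
        if not self.plateau > self.y0:
            raise SpectrumValidationError(
                f"plateau ({self.plateau}) must exceed y0 ({self.y0})"
            )
        if not 0.0 <= self.fit_r2 <= 1.0:
            raise SpectrumValidationError(
                f"fit_r2 must lie in [0, 1], got {self.fit_r2}"
            )
        lo, hi = self.concentration_range_ppb
        self.concentration_range_ppb = (float(lo), float(hi))


class CensoringFlag(str, enum.Enum):
    """Where a quantified concentration sits relative to the assay range."""

    IN_RANGE = "in_range"
    BELOW_LOD = "below_lod"
    ABOVE_RANGE = "above_range"
    UNRESOLVABLE = "unresolvable"


@dataclass
class ConcentrationResult:
    """Final pipeline output for one strip."""

    strip_id: str
    diff: float
    concentration_ppb: float
    censoring_flag: CensoringFlag
    intermediates: dict = field(default_factory=dict)
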