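"""Forward simulator for strip-reader reflectance spectra.

Emulates the measurement chain the analysis pipeline assumes: a broadband
white-LED illuminant, diffuse reflection off the strip, and colloidal-gold
lines that imprint a Gaussian absorbance band near 535 nm (within the
plasmon band printed by gold nanoparticle labels, 520–550 nm):

    S_white(λ) = L(λ) · (1 + ε)
    S_line(λ)  = L(λ) · 10^(−A_line(λ)) · (1 + ε)
    A_line(λ)  = amplitude · exp(−(λ − c)² / 2w²) + baseline_offset

with independent multiplicative Gaussian noise ε of fractional SD 0.25%
per spectrum (the instrument's stated overall noise level). The test-line
amplitude follows competitive inhibition through a truth calibration
model: amplitude_T = amplitude_C · (1 − Diff_truth(concentration)), so the
generative family and the fitted family coincide and parameter recovery is
well posed. In the noiseless case the preprocessing + quantification
pipeline inverts this model exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .models import CalibrationModel, CalibrationPanel, Spectrum, StripScan
from .preprocess import PreprocessConfig
from .quantify import one_phase_association, quantify_strip


def default_truth_model() -> CalibrationModel:
    """Ground-truth standard curve used by the simulator by default."""
    return CalibrationModel(
        y0=0.05,
        plateau=0.95,
        k=1.2,
        fit_r2=1.0,
        n_points=0,
        concentration_range_ppb=(2.5, 100.0),
    )


#: The eight-standard panel design: blank plus seven spiked levels in ppb.
PANEL_CONCENTRATIONS_PPB = (0.0, 2.5, 5.0, 10.0, 25.0, 50.0, 75.0, 100.0)
PANEL_REPLICATES = 5


@dataclass
class SimulatorConfig:
    """Instrument and chemistry parameters of the forward model.

    The spectral grid spans the instrument's 300–1000 nm range at a
    0.55 nm pixel pitch. ``gold_peak_width_nm`` is the Gaussian sigma of
    the plasmon absorbance band; ``noise_fraction`` is the fractional SD
    of the multiplicative intensity noise (default 0.25%).
    """

    grid_start_nm: float = 300.0
    grid_stop_nm: float = 1000.0
    grid_step_nm: float = 0.55
    led_center_nm: float = 560.0
    led_width_nm: float = 180.0
    led_peak_counts: float = 30000.0
    led_floor_fraction: float = 0.02
    gold_peak_center_nm: float = 535.0
    gold_peak_width_nm: float = 40.0
    c_line_amplitude: float = 0.8
    baseline_offset: float = 0.02
    noise_fraction: float = 0.0025
    truth_model: CalibrationModel = field(default_factory=default_truth_model)
    seed: int = 0

    def __post_init__(self):
        if self.grid_step_nm <= 0:
            raise ValueError("grid_step_nm must be > 0")
        if self.noise_fraction < 0:
            raise ValueError("noise_fraction must be >= 0")
        if not 500.0 <= self.gold_peak_center_nm <= 600.0:
            raise ValueError(
                "gold_peak_center_nm must lie in [500, 600] nm"
            )

    def wavelength_grid(self) -> np.ndarray:
        n = int(np.floor((self.grid_stop_nm - self.grid_start_nm) / self.grid_step_nm)) + 1
        return self.grid_start_nm + self.grid_step_nm * np.arange(n)

    def led_profile(self, wavelengths: np.ndarray) -> np.ndarray:
        """Smooth, strictly positive broadband emission curve."""
        z = (wavelengths - self.led_center_nm) / self.led_width_nm
        return self.led_peak_counts * (
            np.exp(-0.5 * z**2) + self.led_floor_fraction
        )

    def gold_band(self, wavelengths: np.ndarray) -> np.ndarray:
        """Unit-height Gaussian plasmon absorbance shape."""
        z = (wavelengths - self.gold_peak_center_nm) / self.gold_peak_width_nm
        return np.exp(-0.5 * z**2)


def diff_truth(config: SimulatorConfig, concentration_ppb: float) -> float:
    """Ground-truth Diff for a concentration under the truth model.

    The blank (0 ppb) is outside the log-concentration domain; it responds
    at the curve floor, max(0, y0), so blank variability in simulations
    arises purely from spectral noise.
    """
    m = config.truth_model
    if concentration_ppb == 0:
        return max(0.0, m.y0)
    return float(
        one_phase_association(
            np.log10(concentration_ppb), m.y0, m.plateau, m.k
        )
    )


def _noisy(values: np.ndarray, rng: np.random.Generator, fraction: float):
    if fraction == 0:
        return values.copy()
    return values * (1.0 + fraction * rng.standard_normal(values.shape))


def simulate_white(
    config: SimulatorConfig, seed: int | np.random.Generator | None = None
) -> Spectrum:
    """One white-reference spectrum, optionally with instrument noise."""
    rng = np.random.default_rng(seed)
    wl = config.wavelength_grid()
    counts = _noisy(config.led_profile(wl), rng, config.noise_fraction)
    return Spectrum(wl, counts, "W")


def simulate_scan(
    concentration_ppb: float,
    config: SimulatorConfig,
    seed: int | np.random.Generator | None = None,
    strip_id: str = "",
) -> StripScan:
    """Simulate one full strip read (C, T and white spectra).

    The three spectra share the LED illuminant and receive independent
    multiplicative noise, as three sequential reads of one strip would.
    """
    if concentration_ppb < 0:
        raise ValueError("concentration must be non-negative")
    rng = np.random.default_rng(seed)
    wl = config.wavelength_grid()
    led = config.led_profile(wl)
    band = config.gold_band(wl)

    amp_c = config.c_line_amplitude
    amp_t = amp_c * (1.0 - diff_truth(config, concentration_ppb))

    def line(amplitude: float, label: str) -> Spectrum:
        absorbance = amplitude * band + config.baseline_offset
        counts = _noisy(led * 10.0 ** (-absorbance), rng, config.noise_fraction)
        return Spectrum(wl, counts, label)

    c_line = line(amp_c, "C")
    t_line = line(amp_t, "T")
    white = Spectrum(wl, _noisy(led, rng, config.noise_fraction), "W")
    return StripScan(
        c_line=c_line,
        t_line=t_line,
        white=white,
        strip_id=strip_id or f"sim-{concentration_ppb:g}ppb",
        nominal_concentration_ppb=float(concentration_ppb),
    )


def generate_panel(
    concentrations: list[float] | None = None,
    replicates: int = PANEL_REPLICATES,
    config: SimulatorConfig | None = None,
    seed: int | None = None,
) -> CalibrationPanel:
    """Simulate a calibration panel: replicate scans at each standard.

    Defaults reproduce the eight-standard, five-replicate design. All
    randomness descends from *seed*; the same seed gives a bit-identical
    panel.
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    concentrations = (
        list(PANEL_CONCENTRATIONS_PPB) if concentrations is None else concentrations
    )
    config = config or SimulatorConfig()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    scans = []
    for conc in concentrations:
        for rep in range(replicates):
            scans.append(
                simulate_scan(
                    conc,
                    config,
                    seed=rng,
                    strip_id=f"panel-{conc:g}ppb-r{rep + 1}",
                )
            )
    return CalibrationPanel(scans)


def generate_method_comparison(
    n_samples: int = 24,
    truth_concs_range: tuple[float, float] = (2.5, 90.0),
    reference_sd_ppb: float = 0.8,
    config: SimulatorConfig | None = None,
    seed: int | None = None,
    model: CalibrationModel | None = None,
    preprocess: PreprocessConfig | None = None,
) -> pd.DataFrame:
    """Paired platform-vs-reference table for method-agreement studies.

    True concentrations are drawn log-uniformly over *truth_concs_range*
    (assay responses are log-linear, so this spreads samples evenly along
    the curve). Platform values run the full spectral pipeline on noisy
    simulated scans against *model* (default: the truth model); reference
    values are truth plus independent Gaussian error of SD
    *reference_sd_ppb*, emulating a confirmatory method with sub-ppb
    precision.
    """
    if n_samples < 3:
        raise ValueError("need >= 3 samples for a method comparison")
    config = config or SimulatorConfig()
    model = model or config.truth_model
    rng = np.random.default_rng(config.seed if seed is None else seed)
    lo, hi = truth_concs_range
    true_concs = 10.0 ** rng.uniform(np.log10(lo), np.log10(hi), n_samples)
    rows = []
    for i, conc in enumerate(true_concs):
        scan = simulate_scan(conc, config, seed=rng, strip_id=f"cmp-{i + 1}")
        result = quantify_strip(scan, model, preprocess)
        reference = conc + reference_sd_ppb * rng.standard_normal()
        rows.append(
            {
                "sample_id": scan.strip_id,
                "true_conc_ppb": float(conc),
                "platform_ppb": result.concentration_ppb,
                "platform_flag": result.censoring_flag.value,
                "reference_ppb": float(reference),
            }
        )
    return pd.DataFrame(rows)
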