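"""Diff statistic, standard-curve fitting/inversion, and detection limits.

The competitive-inhibition response is summarized per strip as

    Diff = 1 − ΔA_T / ΔA_C

which rises from ~0 (blank, strong test line) toward 1 (saturating analyte,
vanished test line). The standard curve is a one-phase association in
x = log10(concentration in ppb):

    Y(x) = y0 + (plateau − y0) · (1 − e^(−k·x))

fitted by nonlinear least squares to the nonzero standards only (log10 of
zero is undefined; blanks are handled separately through the fitted curve
when estimating the limits of blank and detection, LOB = mean + 1.645·SD
and LOD = mean + 3·SD of blank concentrations).
"""

from __future__ import annotations

import math

import numpy as np
from scipy.optimize import least_squares

from .errors import (
    FitFailureError,
    InsufficientDataError,
    InvalidStripError,
    ParameterError,
)
from .models import (
    CalibrationModel,
    CalibrationPanel,
    CensoringFlag,
    ConcentrationResult,
    DiffResult,
    LodResult,
    StripScan,
)
from .preprocess import PreprocessConfig, line_delta_a


def compute_diff(delta_a_t: float, delta_a_c: float) -> DiffResult:
    """Normalized T/C absorbance contrast, Diff = 1 − ΔA_T/ΔA_C.

    The control line is the validity check: ΔA_C must be positive, else the
    strip is void. Negative ΔA_T (blank-strip noise) yields Diff > 1 and is
    retained; clamping is the caller's choice (clamping blanks would bias
    the blank SD, and hence the LOD, downward).
    """
    if not delta_a_c > 0:
        raise InvalidStripError(
            f"control line failed: ΔA_C = {delta_a_c} (must be > 0)"
        )
    return DiffResult(
        delta_a_c=float(delta_a_c),
        delta_a_t=float(delta_a_t),
        diff=1.0 - float(delta_a_t) / float(delta_a_c),
    )


def one_phase_association(
    x: np.ndarray | float, y0: float, plateau: float, k: float
):
    """Y(x) = y0 + (plateau − y0)(1 − e^(−k·x))."""
    return y0 + (plateau - y0) * (1.0 - np.exp(-k * np.asarray(x, dtype=float)))


_K_RESTART_FACTORS = (1.0, 0.1, 10.0, 0.01, 100.0)


def fit_calibration(
    standards: list[tuple[float, float]]
) -> CalibrationModel:
    """Fit the one-phase-association curve to (concentration, Diff) pairs.

    All concentrations must be positive (the 0 ppb blank is excluded from
    the fit). Initialization is deterministic — y0 from the minimum Diff,
    plateau from the maximum, k from the reciprocal x-range — with a fixed
    ladder of k rescalings as restarts, so refitting the same standards
    always returns the same model.
    """
    if not standards:
        raise InsufficientDataError("no calibration standards supplied")
    conc = np.asarray([c for c, _ in standards], dtype=float)
    diffs = np.asarray([d for _, d in standards], dtype=float)
    if np.any(conc <= 0):
        raise ParameterError(
            "calibration standards must have positive concentrations; "
            "the blank is excluded from the fit"
        )
    if len(np.unique(conc)) < 3:
        raise InsufficientDataError(
            "need >= 3 distinct nonzero concentrations to fit 3 parameters, "
            f"got {sorted(set(conc.tolist()))}"
        )
    x = np.log10(conc)
    ss_tot = float(np.sum((diffs - diffs.mean()) ** 2))
    if ss_tot == 0.0:
        raise FitFailureError(
            "flat response: all Diff values identical, curve is unidentifiable",
            diagnostics={"diff_value": float(diffs[0])},
        )

    x_range = float(x.max() - x.min())
    k_init = 1.0 / x_range if x_range > 0 else 1.0
    y0_init, plateau_init = float(diffs.min()), float(diffs.max())
    if plateau_init <= y0_init:  # unreachable given ss_tot > 0, kept for safety
        plateau_init = y0_init + 1e-6

    def residuals(theta):
        y0, plateau, k = theta
        return one_phase_association(x, y0, plateau, k) - diffs

    lower = (-np.inf, -np.inf, 1e-9)
    upper = (np.inf, np.inf, np.inf)
    best = None
    diagnostics = []
    for factor in _K_RESTART_FACTORS:
        theta0 = (y0_init, plateau_init, k_init * factor)
        try:
            sol = least_squares(
                residuals, theta0, bounds=(lower, upper), method="trf"
            )
        except Exception as exc:  # numerical blow-up in a restart
            diagnostics.append({"k_factor": factor, "error": str(exc)})
            continue
        y0, plateau, k = sol.x
        diagnostics.append(
            {"k_factor": factor, "cost": float(sol.cost), "success": sol.success}
        )
        if not sol.success or not (plateau > y0 and k > 0):
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None:
        raise FitFailureError(
            "one-phase-association fit failed for every restart",
            diagnostics={"restarts": diagnostics},
        )
    y0, plateau, k = (float(v) for v in best.x)
    ss_res = float(np.sum(residuals(best.x) ** 2))
    r2 = 1.0 - ss_res / ss_tot
    return CalibrationModel(
        y0=y0,
        plateau=plateau,
        k=k,
        fit_r2=max(0.0, min(1.0, r2)),
        n_points=len(standards),
        concentration_range_ppb=(float(conc.min()), float(conc.max())),
    )


def predict_diff(model: CalibrationModel, concentration_ppb: float) -> float:
    """Forward-evaluate the standard curve at a positive concentration."""
    if not concentration_ppb > 0:
        raise ParameterError(
            f"concentration must be positive, got {concentration_ppb}"
        )
    return float(
        one_phase_association(
            math.log10(concentration_ppb), model.y0, model.plateau, model.k
        )
    )


def invert_concentration(
    model: CalibrationModel, diff: float, strip_id: str = ""
) -> ConcentrationResult:
    """Invert the standard curve; always returns a flagged result.

    * y0 < diff < plateau — closed-form inversion, flag ``in_range``
      (or ``below_lod`` when the model carries a detection limit and the
      concentration falls below it);
    * diff == y0 — x = 0, i.e. exactly 1 ppb;
    * diff < y0 — reported as 0 ppb, ``below_lod``;
    * diff >= plateau — censored at the calibration upper bound,
      ``above_range``;
    * non-finite diff — ``unresolvable``.
    """
    upper = model.concentration_range_ppb[1]
    if not math.isfinite(diff):
        return ConcentrationResult(
            strip_id, float(diff), float("nan"), CensoringFlag.UNRESOLVABLE
        )
    if diff < model.y0:
        return ConcentrationResult(strip_id, diff, 0.0, CensoringFlag.BELOW_LOD)
    if diff >= model.plateau:
        return ConcentrationResult(
            strip_id, diff, upper, CensoringFlag.ABOVE_RANGE
        )
    x = -math.log1p(-(diff - model.y0) / (model.plateau - model.y0)) / model.k
    concentration = 10.0**x
    flag = CensoringFlag.IN_RANGE
    if model.lod is not None and concentration < model.lod.lod_ppb:
        flag = CensoringFlag.BELOW_LOD
    return ConcentrationResult(strip_id, diff, concentration, flag)


def estimate_lob_lod(blank_concentrations_ppb: list[float]) -> LodResult:
    """Limits of blank and detection from blank replicate concentrations.

    LOB = mean + 1.645·SD is the 95% one-sided upper limit of the blank
    distribution; LOD = mean + 3·SD. The SD uses the n−1 denominator.
    """
    blanks = np.asarray(blank_concentrations_ppb, dtype=float)
    if blanks.size < 2:
        raise InsufficientDataError(
            f"need >= 2 blank replicates, got {blanks.size}"
        )
    mean = float(blanks.mean())
    sd = float(blanks.std(ddof=1))
    return LodResult(
        blank_mean_ppb=mean,
        blank_sd_ppb=sd,
        lob_ppb=mean + 1.645 * sd,
        lod_ppb=mean + 3.0 * sd,
        n_blanks=int(blanks.size),
    )


def blank_concentration(model: CalibrationModel, diff: float) -> float:
    """Map a blank strip's Diff to the concentration scale for LOB/LOD.

    Diff at or below the curve floor y0 maps to 0 ppb; above the floor the
    standard inversion applies. Detection limits are computed on the
    concentration scale because they are reported in ppb.
    """
    if diff <= model.y0:
        return 0.0
    return invert_concentration(model, diff).concentration_ppb


def quantify_strip(
    scan: StripScan,
    model: CalibrationModel,
    config: PreprocessConfig | None = None,
) -> ConcentrationResult:
    """Full per-strip pipeline: absorbance → smoothing → ΔA → Diff → ppb.

    Intermediate peak and Diff values are recorded on the result for audit.
    """
    config = config or PreprocessConfig()
    peak_c = line_delta_a(scan.c_line, scan.white, config)
    peak_t = line_delta_a(scan.t_line, scan.white, config)
    diff = compute_diff(peak_t.delta_a, peak_c.delta_a)
    result = invert_concentration(model, diff.diff, strip_id=scan.strip_id)
    result.intermediates = {
        "delta_a_c": peak_c.delta_a,
        "delta_a_t": peak_t.delta_a,
        "peak_wavelength_c_nm": peak_c.peak_wavelength_nm,
        "peak_wavelength_t_nm": peak_t.peak_wavelength_nm,
        "diff": diff.diff,
    }
    return result


def panel_diffs(
    panel: CalibrationPanel, config: PreprocessConfig | None = None
) -> list[tuple[float, float]]:
    """(nominal concentration, measured Diff) for every scan of a panel."""
    config = config or PreprocessConfig()
    out = []
    for scan in panel.scans:
        peak_c = line_delta_a(scan.c_line, scan.white, config)
        peak_t = line_delta_a(scan.t_line, scan.white, config)
        diff = compute_diff(peak_t.delta_a, peak_c.delta_a)
        out.append((scan.nominal_concentration_ppb, diff.diff))
    return out


def calibrate_panel(
    panel: CalibrationPanel,
    config: PreprocessConfig | None = None,
    attach_lod: bool = True,
) -> CalibrationModel:
    """Fit the standard curve from a calibration panel of strip scans.

    Nonzero standards feed the fit; blank (0 ppb) scans, if present in
    sufficient number, are pushed through the fitted curve to estimate and
    attach LOB/LOD.
    """
    pairs = panel_diffs(panel, config)
    nonzero = [(c, d) for c, d in pairs if c > 0]
    model = fit_calibration(nonzero)
    blanks = [d for c, d in pairs if c == 0]
    if attach_lod and len(blanks) >= 2:
        blank_concs = [blank_concentration(model, d) for d in blanks]
        model.lod = estimate_lob_lod(blank_concs)
    return model
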