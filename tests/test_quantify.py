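"""Diff statistic, standard-curve fit/inversion, LOB/LOD, per-strip pipeline."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from stripspec import (
    CalibrationModel,
    CensoringFlag,
    FitFailureError,
    InsufficientDataError,
    InvalidStripError,
    ParameterError,
    SimulatorConfig,
    Spectrum,
    StripScan,
    blank_concentration,
    compute_diff,
    estimate_lob_lod,
    fit_calibration,
    invert_concentration,
    one_phase_association,
    predict_diff,
    quantify_strip,
    simulate_scan,
)

SEVEN_STANDARDS = [2.5, 5.0, 10.0, 25.0, 50.0, 75.0, 100.0]


class TestComputeDiff:
    @pytest.mark.parametrize(
        "da_t,da_c,expected",
        [(0.5, 0.5, 0.0), (0.0, 0.5, 1.0), (0.3, 0.6, 0.5)],
    )
    def test_arithmetic(self, da_t, da_c, expected):
        assert compute_diff(da_t, da_c).diff == pytest.approx(expected)

    def test_failed_control_line(self):
        with pytest.raises(InvalidStripError):
            compute_diff(0.5, 0.0)

    def test_negative_t_line_retained_above_one(self):
        # blank-strip noise can push ΔA_T below zero; Diff > 1 is kept
        assert compute_diff(-0.01, 0.5).diff > 1.0


def _standards_from(model_params, concs=SEVEN_STANDARDS):
    y0, plateau, k = model_params
    return [
        (c, float(one_phase_association(math.log10(c), y0, plateau, k)))
        for c in concs
    ]


class TestFitCalibration:
    def test_noiseless_recovery(self):
        truth = (0.05, 0.95, 1.2)
        model = fit_calibration(_standards_from(truth))
        assert model.y0 == pytest.approx(truth[0], rel=1e-6)
        assert model.plateau == pytest.approx(truth[1], rel=1e-6)
        assert model.k == pytest.approx(truth[2], rel=1e-6)
        assert model.fit_r2 == pytest.approx(1.0, abs=1e-12)
        assert model.concentration_range_ppb == (2.5, 100.0)

    def test_replicated_noisy_standards_high_r2(self):
        rng = np.random.default_rng(123)
        standards = []
        for _ in range(5):
            for c, d in _standards_from((0.05, 0.95, 1.2)):
                standards.append((c, d * (1 + rng.normal(0, 0.0025))))
        model = fit_calibration(standards)
        assert model.fit_r2 >= 0.99
        assert model.n_points == 35

    def test_flat_response_fails(self):
        with pytest.raises(FitFailureError):
            fit_calibration([(c, 0.5) for c in SEVEN_STANDARDS])

    def test_too_few_distinct_concentrations(self):
        with pytest.raises(InsufficientDataError):
            fit_calibration([(2.5, 0.1), (2.5, 0.2), (100.0, 0.9)])

    def test_zero_concentration_rejected(self):
        with pytest.raises(ParameterError):
            fit_calibration([(0.0, 0.05), (10.0, 0.6), (100.0, 0.9)])

    def test_fit_is_deterministic(self):
        rng = np.random.default_rng(5)
        standards = [
            (c, d + rng.normal(0, 0.002))
            for c, d in _standards_from((0.1, 0.9, 1.0))
        ]
        a = fit_calibration(standards)
        b = fit_calibration(standards)
        assert (a.y0, a.plateau, a.k) == (b.y0, b.plateau, b.k)


class TestPredictInvert:
    @pytest.fixture
    def model(self):
        return CalibrationModel(0.1, 0.9, 1.0, 1.0, 7, (2.5, 100.0))

    def test_predict_at_one_ppb_is_y0(self, model):
        assert predict_diff(model, 1.0) == pytest.approx(0.1)

    def test_predict_approaches_plateau(self, model):
        assert predict_diff(model, 1e30) == pytest.approx(0.9, abs=1e-9)

    def test_predict_closed_form_at_10ppb(self, model):
        assert predict_diff(model, 10.0) == pytest.approx(
            0.1 + 0.8 * (1 - math.exp(-1)), rel=1e-12
        )

    def test_predict_rejects_nonpositive(self, model):
        with pytest.raises(ParameterError):
            predict_diff(model, 0.0)

    @pytest.mark.parametrize("conc", [2.5, 10.0, 100.0])
    def test_invert_predict_round_trip(self, model, conc):
        res = invert_concentration(model, predict_diff(model, conc))
        assert res.concentration_ppb == pytest.approx(conc, rel=1e-9)
        assert res.censoring_flag == CensoringFlag.IN_RANGE

    def test_diff_at_floor_maps_to_one_ppb(self, model):
        res = invert_concentration(model, model.y0)
        assert res.concentration_ppb == pytest.approx(1.0)
        assert res.censoring_flag == CensoringFlag.IN_RANGE

    def test_diff_below_floor_censored_at_zero(self, model):
        res = invert_concentration(model, 0.05)
        assert res.concentration_ppb == 0.0
        assert res.censoring_flag == CensoringFlag.BELOW_LOD

    def test_diff_above_plateau_censored_at_range_top(self, model):
        res = invert_concentration(model, 0.99)
        assert res.concentration_ppb == 100.0
        assert res.censoring_flag == CensoringFlag.ABOVE_RANGE

    def test_non_finite_diff_unresolvable(self, model):
        res = invert_concentration(model, float("nan"))
        assert res.censoring_flag == CensoringFlag.UNRESOLVABLE

    @given(
        y0=st.floats(min_value=-0.2, max_value=0.3, allow_nan=False),
        span=st.floats(min_value=0.1, max_value=1.0, allow_nan=False),
        k=st.floats(min_value=0.05, max_value=10.0, allow_nan=False),
        c1=st.floats(min_value=1.1, max_value=500.0, allow_nan=False),
        factor=st.floats(min_value=1.01, max_value=10.0, allow_nan=False),
    )
    def test_predict_strictly_increasing(self, y0, span, k, c1, factor):
        model = CalibrationModel(y0, y0 + span, k, 1.0, 7, (2.5, 100.0))
        assert predict_diff(model, c1 * factor) > predict_diff(model, c1)

    @given(
        y0=st.floats(min_value=-0.2, max_value=0.3, allow_nan=False),
        span=st.floats(min_value=0.1, max_value=1.0, allow_nan=False),
        k=st.floats(min_value=0.05, max_value=10.0, allow_nan=False),
        frac=st.floats(min_value=1e-6, max_value=1 - 1e-6, allow_nan=False),
    )
    def test_invert_is_exact_inverse_on_open_interval(
        self, y0, span, k, frac
    ):
        model = CalibrationModel(y0, y0 + span, k, 1.0, 7, (2.5, 100.0))
        diff = y0 + frac * span
        res = invert_concentration(model, diff)
        assert predict_diff(model, res.concentration_ppb) == pytest.approx(
            diff, abs=1e-9
        )


class TestLobLod:
    def test_all_zero_blanks(self):
        res = estimate_lob_lod([0.0, 0.0, 0.0])
        assert res.lob_ppb == 0.0
        assert res.lod_ppb == 0.0

    def test_mean_one_sd_one(self):
        # five-point sample with mean 1 and (n-1)-denominator SD exactly 1
        blanks = [1.0 - math.sqrt(2), 1.0, 1.0, 1.0, 1.0 + math.sqrt(2)]
        res = estimate_lob_lod(blanks)
        assert res.blank_mean_ppb == pytest.approx(1.0)
        assert res.blank_sd_ppb == pytest.approx(1.0)
        assert res.lob_ppb == pytest.approx(2.645)
        assert res.lod_ppb == pytest.approx(4.0)

    def test_reported_detection_limit_from_blank_summary(self):
        """Blanks with mean 1.53 ppb and SD 0.13 ppb give LOD 1.91±0.02 ppb."""
        a = 0.13 * math.sqrt(3.0) / 2.0
        blanks = [1.53 - a, 1.53 - a, 1.53 + a, 1.53 + a]
        res = estimate_lob_lod(blanks)
        assert res.blank_mean_ppb == pytest.approx(1.53, abs=1e-12)
        assert res.blank_sd_ppb == pytest.approx(0.13, abs=1e-12)
        assert res.lod_ppb == pytest.approx(1.91, abs=0.02)
        assert res.lob_ppb == pytest.approx(1.53 + 1.645 * 0.13, abs=1e-9)

    def test_single_blank_insufficient(self):
        with pytest.raises(InsufficientDataError):
            estimate_lob_lod([0.5])

    @given(
        shift=st.floats(min_value=-5, max_value=5, allow_nan=False),
        blanks=st.lists(
            st.floats(min_value=0, max_value=3, allow_nan=False),
            min_size=2,
            max_size=20,
        ),
    )
    def test_shift_equivariance_and_ordering(self, shift, blanks):
        base = estimate_lob_lod(blanks)
        shifted = estimate_lob_lod([b + shift for b in blanks])
        assert shifted.lob_ppb == pytest.approx(base.lob_ppb + shift, abs=1e-8)
        assert shifted.lod_ppb == pytest.approx(base.lod_ppb + shift, abs=1e-8)
        assert base.lod_ppb >= base.lob_ppb >= base.blank_mean_ppb


class TestQuantifyStrip:
    def test_noiseless_scan_recovers_concentration(
        self, noiseless_config, truth_model
    ):
        scan = simulate_scan(10.0, noiseless_config, seed=0)
        res = quantify_strip(scan, truth_model)
        assert res.concentration_ppb == pytest.approx(10.0, rel=1e-6)
        assert res.censoring_flag == CensoringFlag.IN_RANGE
        assert "delta_a_c" in res.intermediates

    def test_blank_scan_flags_below_lod(self, noiseless_config, truth_model):
        # blank responds at the curve floor; a fitted LOD above 1 ppb censors it
        truth_model.lod = estimate_lob_lod([1.4, 1.5, 1.6])
        scan = simulate_scan(0.0, noiseless_config, seed=0)
        res = quantify_strip(scan, truth_model)
        assert res.censoring_flag == CensoringFlag.BELOW_LOD

    def test_c_line_equal_white_is_invalid_strip(
        self, noiseless_config, truth_model
    ):
        scan = simulate_scan(10.0, noiseless_config, seed=0)
        bad = StripScan(
            c_line=Spectrum(
                scan.white.wavelengths_nm, scan.white.intensities, "C"
            ),
            t_line=scan.t_line,
            white=scan.white,
            strip_id="bad",
        )
        with pytest.raises(InvalidStripError):
            quantify_strip(bad, truth_model)


class TestBlankConcentration:
    def test_floor_maps_to_zero(self, truth_model):
        assert blank_concentration(truth_model, truth_model.y0) == 0.0
        assert blank_concentration(truth_model, truth_model.y0 - 0.1) == 0.0

    def test_above_floor_uses_inversion(self, truth_model):
        diff = predict_diff(truth_model, 3.0)
        assert blank_concentration(truth_model, diff) == pytest.approx(3.0)
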