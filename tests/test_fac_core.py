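"""FAC quantitation math: forward model, inversion, calibration fit."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from facprof import (
    CalibrationPoint,
    bed_volume_uL,
    ka_from_kd,
    kd_from_retardation,
    kd_simplified,
    retardation_forward,
    simulate_calibration_series,
    woolf_hofstee_fit,
)
from facprof.errors import (
    InsufficientDataError,
    NoSaturableBindingError,
    ValidationError,
)

A0 = 2.5e-9  # standard PA-glycan infusion concentration, M


class TestForwardModel:
    @pytest.mark.parametrize(
        "bt,kd,a0,expected",
        [
            (0.63, 3.01e-5, A0, 20.93),  # PPL3s column, calibration ligand
            (0.98, 2.0e-5, A0, 48.99),  # PPL4 column
            (0.0, 1e-5, A0, 0.0),  # no ligand, no retardation
        ],
    )
    def test_worked_examples(self, bt, kd, a0, expected):
        assert retardation_forward(bt, kd, a0) == pytest.approx(expected, abs=5e-3)

    def test_unit_identity(self):
        # 1 nmol / 1 mL = 1 uM: the uL * (mmol/L) = nmol conversion
        assert kd_simplified(1.0, 1000.0) == pytest.approx(1e-6)

    @given(
        bt=st.floats(1e-3, 10.0),
        kd=st.floats(1e-8, 1e-3),
        a0=st.floats(1e-10, 1e-8),
    )
    @settings(deadline=None, derandomize=True)
    def test_round_trip_closes(self, bt, kd, a0):
        v = retardation_forward(bt, kd, a0)
        assert kd_from_retardation(bt, v, a0) == pytest.approx(kd, rel=1e-9)

    @given(
        bt=st.floats(1e-3, 10.0),
        kd=st.floats(1e-8, 1e-3),
        a0=st.floats(0.0, 1e-8),
    )
    @settings(deadline=None, derandomize=True)
    def test_monotonicity(self, bt, kd, a0):
        v = retardation_forward(bt, kd, a0)
        assert retardation_forward(bt, kd * 1.5, a0) < v
        assert retardation_forward(bt, kd, a0 + 1e-9) < v
        assert retardation_forward(bt * 2, kd, a0) == pytest.approx(2 * v, rel=1e-12)

    def test_invalid_inputs(self):
        with pytest.raises(ValidationError):
            retardation_forward(-1.0, 1e-5, A0)
        with pytest.raises(ValidationError):
            retardation_forward(1.0, 0.0, A0)


class TestInversion:
    def test_ppl3s_round_trip_value(self):
        assert kd_from_retardation(0.63, 20.93, A0) == pytest.approx(
            3.01e-5, rel=1e-3
        )

    def test_ppl2a_round_trip_value(self):
        assert kd_from_retardation(0.02, 98.77, A0) == pytest.approx(2.0e-7, rel=1e-3)

    def test_below_detection_returns_none(self):
        assert kd_from_retardation(0.63, 0.0, A0) is None
        assert kd_from_retardation(0.63, -1.2, A0) is None
        assert kd_simplified(0.63, -0.1) is None

    def test_noise_exceeding_model_returns_none(self):
        # huge retardation at tiny Bt implies negative Kd
        assert kd_from_retardation(1e-3, 1e9, 1e-5) is None

    def test_simplified_error_is_exactly_a0(self):
        v = retardation_forward(0.63, 3.01e-5, A0)
        full = kd_from_retardation(0.63, v, A0)
        approx = kd_simplified(0.63, v)
        assert approx - full == pytest.approx(A0, rel=1e-9)
        assert (approx - full) / full == pytest.approx(A0 / full, rel=1e-9)

    @pytest.mark.parametrize("kd", [2e-7, 1e-6, 3.01e-5])
    def test_simplified_deviation_below_1p3_percent(self, kd):
        """A0/Kd bound: < 1.3% whenever A0 = 2.5 nM and Kd >= 2e-7 M."""
        v = retardation_forward(0.63, kd, A0)
        full = kd_from_retardation(0.63, v, A0)
        approx = kd_simplified(0.63, v)
        assert abs(approx - full) / full < 0.013


class TestKa:
    def test_reciprocal(self):
        assert ka_from_kd(2.0e-7) == pytest.approx(5.0e6)
        assert ka_from_kd(3.01e-5) == pytest.approx(3.322e4, rel=1e-3)

    def test_nonpositive_kd_rejected(self):
        with pytest.raises(ValidationError):
            ka_from_kd(0.0)


class TestWoolfHofstee:
    @pytest.mark.parametrize(
        "bt,kd",
        [(0.63, 3.01e-5), (0.98, 2.0e-5), (0.02, 2.0e-7)],
        ids=["PPL3s", "PPL4", "PPL2A"],
    )
    def test_noiseless_recovery_exact(self, bt, kd):
        points = [
            CalibrationPoint(f * kd, retardation_forward(bt, kd, f * kd))
            for f in (0.1, 0.3, 1.0, 3.0, 10.0)
        ]
        cal = woolf_hofstee_fit(points)
        assert cal.kd_ref_M == pytest.approx(kd, rel=1e-6)
        assert cal.bt_nmol == pytest.approx(bt, rel=1e-6)
        assert cal.r2 == pytest.approx(1.0, abs=1e-9)

    def test_noisy_recovery_median_error(self):
        """2% multiplicative noise: median |Kd error| < 10% over 500 fits."""
        errors = []
        for seed in range(500):
            pts = simulate_calibration_series(
                0.63, 3.01e-5, noise_cv=0.02, seed=seed
            )
            cal = woolf_hofstee_fit(pts)
            errors.append(abs(cal.kd_ref_M - 3.01e-5) / 3.01e-5)
        assert np.median(errors) < 0.10

    def test_too_few_points(self):
        pts = [CalibrationPoint(1e-5, 10.0), CalibrationPoint(2e-5, 8.0)]
        with pytest.raises(InsufficientDataError):
            woolf_hofstee_fit(pts)

    def test_degenerate_duplicated_points(self):
        pts = [CalibrationPoint(1e-5, 10.0)] * 5
        with pytest.raises(InsufficientDataError):
            woolf_hofstee_fit(pts)

    def test_positive_slope_is_no_saturable_binding(self):
        # retardation increasing with concentration contradicts saturation
        pts = [
            CalibrationPoint(1e-6, 5.0),
            CalibrationPoint(1e-5, 10.0),
            CalibrationPoint(1e-4, 20.0),
        ]
        with pytest.raises(NoSaturableBindingError):
            woolf_hofstee_fit(pts)


def test_bed_volume_of_miniature_column():
    # cylinder, diameter 2 mm x length 10 mm
    assert bed_volume_uL(2.0, 10.0) == pytest.approx(31.416, abs=1e-3)
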