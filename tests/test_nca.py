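"""Non-compartmental analysis: AUC, half-life, clearance, dose proportionality."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from nanopbpk.model import InvalidInputError
from nanopbpk.nca import (
    auc_trapezoid,
    c0_extrapolate,
    clearance,
    dose_proportionality_slope,
    nca_profile,
    nca_table,
    relative_exposure,
    terminal_half_life,
)

# published plasma NCA rows: (dose mg/kg, total AUC, released AUC)
TABLE_PAIRS = [
    (10, 2294, 38.7),
    (55, 19593, 373),
    (110, 40187, 694),
    (505, 136989, 1714),
    (12, 1812, 56.3),
]


class TestAuc:
    def test_rectangle(self):
        assert auc_trapezoid([0, 1], [10, 10], "linear") == pytest.approx(10.0)

    def test_triangle(self):
        assert auc_trapezoid([0, 1], [10, 0], "linear") == pytest.approx(5.0)

    def test_log_down_matches_exponential_integral(self):
        t = np.arange(0, 10.01, 0.5)
        c = np.exp(-t)
        auc = auc_trapezoid(t, c, "linuplogdown")
        assert auc == pytest.approx(1 - math.exp(-10), rel=1e-6)

    def test_linear_overestimates_exponential_decline(self):
        t = np.arange(0, 10.01, 0.5)
        c = np.exp(-t)
        assert auc_trapezoid(t, c, "linear") > auc_trapezoid(t, c, "linuplogdown")

    def test_unsorted_times_rejected(self):
        with pytest.raises(InvalidInputError):
            auc_trapezoid([0, 2, 1], [1, 1, 1])

    @given(
        st.lists(st.floats(min_value=0.01, max_value=100), min_size=2, max_size=12)
    )
    def test_linear_auc_matches_numpy_trapezoid(self, concentrations):
        t = np.arange(len(concentrations), dtype=float)
        c = np.array(concentrations)
        assert auc_trapezoid(t, c, "linear") == pytest.approx(
            float(np.trapezoid(c, t))
        )


class TestHalfLife:
    def test_monoexponential(self):
        t = np.arange(0, 48.1, 4.0)
        c = 100 * np.exp(-0.0693 * t)
        hl = terminal_half_life(t, c)
        assert hl.half_life == pytest.approx(10.0, rel=1e-3)
        assert hl.reliable

    def test_flat_profile_not_estimable(self):
        hl = terminal_half_life([0, 1, 2, 3], [5.0, 5.0, 5.0, 5.0])
        assert not hl.estimable

    def test_biexponential_terminal_phase(self):
        t = np.arange(12, 73, 12.0)
        c = 5 * np.exp(-1.0 * t) + 1 * np.exp(-0.1 * t)
        hl = terminal_half_life(t, c)
        assert hl.half_life == pytest.approx(math.log(2) / 0.1, rel=0.01)

    def test_too_few_points_not_estimable(self):
        hl = terminal_half_life([0, 1, 2], [10.0, 5.0, 0.0])
        assert not hl.estimable
        assert "positive" in hl.reason


class TestClearance:
    @pytest.mark.parametrize(
        "dose, auc, expected",
        [(10, 38.7, 0.258), (50, 28, 1.786), (7.0, 7.0, 1.0)],
    )
    def test_dose_over_auc(self, dose, auc, expected):
        assert clearance(dose, auc) == pytest.approx(expected, rel=1e-2)

    def test_zero_auc_rejected(self):
        with pytest.raises(InvalidInputError):
            clearance(10, 0.0)

    def test_clearance_auc_identity_on_profile(self):
        t = np.arange(0, 24.1, 1.0)
        c = 8 * np.exp(-0.3 * t)
        res = nca_profile(t, c, dose=5.0)
        assert res.CL * res.AUC_last == pytest.approx(5.0, rel=1e-12)
        assert res.AUC_inf >= res.AUC_last


class TestDoseProportionality:
    def test_total_api_slope(self):
        doses = [p[0] for p in TABLE_PAIRS]
        slope = dose_proportionality_slope(doses, [p[1] for p in TABLE_PAIRS])
        assert slope == pytest.approx(276.4, rel=1e-3)

    def test_released_api_slope(self):
        doses = [p[0] for p in TABLE_PAIRS]
        slope = dose_proportionality_slope(doses, [p[2] for p in TABLE_PAIRS])
        assert slope == pytest.approx(3.56, rel=1e-2)

    def test_single_pair(self):
        assert dose_proportionality_slope([4.0], [10.0]) == pytest.approx(2.5)

    @given(st.floats(min_value=0.1, max_value=10))
    def test_scale_equivariance(self, factor):
        doses = [p[0] for p in TABLE_PAIRS]
        aucs = [p[1] for p in TABLE_PAIRS]
        base = dose_proportionality_slope(doses, aucs)
        scaled = dose_proportionality_slope(doses, [a * factor for a in aucs])
        assert scaled == pytest.approx(base * factor, rel=1e-9)

    def test_all_zero_doses_rejected(self):
        with pytest.raises(InvalidInputError):
            dose_proportionality_slope([0.0, 0.0], [1.0, 2.0])


class TestRelativeExposure:
    def test_rat_arithmetic(self):
        assert relative_exposure(373 / 55, 28 / 50) == pytest.approx(1211, rel=1e-3)

    def test_dog_arithmetic(self):
        assert relative_exposure(56.3 / 12, 8.9 / 12) == pytest.approx(633, rel=1e-2)

    def test_equal_exposures(self):
        assert relative_exposure(3.3, 3.3) == pytest.approx(100.0)

    def test_zero_denominator_rejected(self):
        with pytest.raises(InvalidInputError):
            relative_exposure(1.0, 0.0)


class TestC0AndTable:
    def test_c0_backextrapolation(self):
        t = np.array([0.25, 0.5, 1.0, 2.0])
        c = 20 * np.exp(-0.5 * t)
        assert c0_extrapolate(t, c) == pytest.approx(20.0, rel=1e-6)

    def test_nca_table_on_simulated_profile(self, mouse_course):
        frame = mouse_course.to_frame()
        frame["subject_id"] = "sim"
        table = nca_table(frame)
        plasma = table[(table.matrix == "plasma") & (table.analyte == "total")]
        assert len(plasma) == 1
        row = plasma.iloc[0]
        assert row.CL_L_h_kg * row.AUC_last == pytest.approx(10.0, rel=1e-12)
        # total exposure dwarfs released exposure
        rel_row = table[(table.matrix == "plasma") & (table.analyte == "released")]
        assert row.AUC_last / rel_row.iloc[0].AUC_last > 10

    def test_simulated_half_life_on_study_schedule_in_printed_envelope(
        self, mouse, schedule_course
    ):
        course = schedule_course(mouse, [1 / 3, 1, 6, 24, 48, 72, 96])
        hl = terminal_half_life(
            course.times, course.concentration("plasma", "total")
        )
        assert 6.8 <= hl.half_life <= 15.0
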