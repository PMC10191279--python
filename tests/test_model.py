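"""Core PBPK model: partition coefficients, right-hand sides, simulation."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from dataclasses import replace

import nanopbpk as nb
from nanopbpk.model import (
    InvalidInputError,
    conjugated_rhs,
    partition_coefficient,
    released_rhs,
    rest_volume,
    total_from_components,
)


class TestPartitionCoefficient:
    @pytest.mark.parametrize(
        "c, triple, expected",
        [
            (0.0, (49.6, 0.6, 0.76), 83.4267),  # mouse liver, zero conc
            (0.0, (125.9, 0.63, 0.17), 200.0095),  # mouse spleen, zero conc
        ],
    )
    def test_zero_concentration_limit(self, c, triple, expected):
        assert partition_coefficient(c, *triple) == pytest.approx(expected, rel=1e-4)

    def test_saturation_limit_is_nonspecific_term(self):
        assert partition_coefficient(1e9, 49.6, 0.6, 0.76) == pytest.approx(
            0.76, rel=1e-4
        )

    @given(st.floats(min_value=0, max_value=1e3), st.floats(min_value=1e-6, max_value=10))
    def test_monotone_decreasing_in_concentration(self, c, dc):
        lo = partition_coefficient(c + dc, 49.6, 0.6, 0.76)
        hi = partition_coefficient(c, 49.6, 0.6, 0.76)
        assert lo < hi

    def test_invalid_inputs_rejected(self):
        with pytest.raises(InvalidInputError):
            partition_coefficient(-1.0, 49.6, 0.6, 0.76)
        with pytest.raises(InvalidInputError):
            partition_coefficient(1.0, 49.6, 0.0, 0.76)


class TestRightHandSides:
    def test_empty_system_is_at_equilibrium(self, mouse):
        zero = np.zeros(4)
        assert np.all(
            released_rhs(zero, zero, mouse.released, mouse.conjugated, mouse.physiology)
            == 0
        )
        assert np.all(conjugated_rhs(zero, mouse.conjugated, mouse.physiology) == 0)

    def test_released_mass_conserved_without_clearance_or_release(self, mouse):
        rel = replace(mouse.released, CL=0.0)
        conj = replace(
            mouse.conjugated, krel_b=0.0, krel_L=0.0, krel_S=0.0, krel_R=0.0
        )
        a = np.array([0.3, 1.1, 0.05, 0.2])
        x = np.array([2.0, 0.4, 0.1, 0.0])
        da = released_rhs(a, x, rel, conj, mouse.physiology)
        assert da.sum() == pytest.approx(0.0, abs=1e-12)

    def test_blood_efflux_rate_matches_hand_evaluation(self, mouse):
        # A_b = 1 mg/kg alone: outflow (Q_BL_i + Q_BS + Q_BR)/V_b
        a = np.array([1.0, 0.0, 0.0, 0.0])
        da = released_rhs(a, np.zeros(4), mouse.released, mouse.conjugated,
                          mouse.physiology)
        assert da[0] == pytest.approx(-(8.36 + 0.74 + 0.015) / 0.34, rel=1e-6)

    def test_released_derivative_sum_identity(self, mouse):
        # sum of dA/dt = sum(krel_x X_x) - CL*A_L/(V_L*K_BL)
        a = np.array([0.5, 0.8, 0.12, 0.3])
        x = np.array([1.5, 0.6, 0.2, 0.1])
        rel, conj, ph = mouse.released, mouse.conjugated, mouse.physiology
        da = released_rhs(a, x, rel, conj, ph)
        k_bl = partition_coefficient(a[0] / rel.V_b, rel.Bmax_L, rel.KD_L, rel.P_L)
        release = (
            conj.krel_b * x[0] + conj.krel_L * x[1]
            + conj.krel_S * x[2] + conj.krel_R * x[3]
        )
        elimination = rel.CL * a[1] / (ph.V_L * k_bl)
        assert da.sum() == pytest.approx(release - elimination, rel=1e-10)

    def test_conjugated_blood_decay_matches_hand_evaluation(self, mouse):
        x = np.array([1.0, 0.0, 0.0, 0.0])
        dx = conjugated_rhs(x, mouse.conjugated, mouse.physiology)
        assert dx[0] == pytest.approx(-(0.0003 + 2e-5) / 0.085 - 0.125, rel=1e-6)

    def test_conjugated_sum_is_total_release_loss(self, mouse):
        x = np.array([0.9, 0.5, 0.3, 0.0])
        conj = mouse.conjugated
        dx = conjugated_rhs(x, conj, mouse.physiology)
        loss = (
            conj.krel_b * x[0] + conj.krel_L * x[1]
            + conj.krel_S * x[2] + conj.krel_R * x[3]
        )
        assert dx.sum() == pytest.approx(-loss, rel=1e-10)

    def test_rest_compartment_inert_when_nbr_zero(self, mouse):
        # N_BR = 0 and X_R(0) = 0: nothing ever reaches the conjugated rest pool
        x = np.array([1.0, 0.2, 0.1, 0.0])
        dx = conjugated_rhs(x, mouse.conjugated, mouse.physiology)
        assert dx[3] == 0.0


class TestTotals:
    def test_totals_equal_released_when_no_conjugate(self, mouse):
        # zero conjugate: plasma total = plasma released exactly; tissue totals
        # add only the vascular blood contribution v_tissue * C_blood
        released = {
            "blood": np.zeros(2),
            "plasma": np.array([1.0, 2.0]),
            "liver": np.array([1.0, 2.0]),
            "spleen": np.array([1.0, 2.0]),
        }
        x = {k: np.zeros(2) for k in ("X_b", "X_L", "X_S")}
        totals = total_from_components(released, x, mouse.physiology, mouse.conjugated)
        for m in ("plasma", "liver", "spleen"):
            np.testing.assert_allclose(totals[m], released[m])
        released["blood"] = np.array([4.0, 4.0])
        totals = total_from_components(released, x, mouse.physiology, mouse.conjugated)
        np.testing.assert_allclose(totals["liver"], released["liver"] + 0.125 * 4.0)

    def test_plasma_total_uses_plasma_water_fraction(self, mouse):
        ph = replace(mouse.physiology, H=0.45)
        released = {m: np.zeros(1) for m in ("blood", "plasma", "liver", "spleen")}
        x = {"X_b": np.array([ph.V_Nb]), "X_L": np.zeros(1), "X_S": np.zeros(1)}
        totals = total_from_components(released, x, ph, mouse.conjugated)
        assert totals["plasma"][0] == pytest.approx(0.55)

    def test_liver_total_adds_vascular_blood(self, mouse):
        ph = mouse.physiology  # v_liver = 0.125
        released = {m: np.zeros(1) for m in ("blood", "plasma", "liver", "spleen")}
        x = {
            "X_b": np.array([2.0 * ph.V_Nb]),  # C_blood_tot = 2
            "X_L": np.array([3.0 * ph.V_L]),  # X_L/V_L = 3
            "X_S": np.zeros(1),
        }
        totals = total_from_components(released, x, ph, mouse.conjugated)
        assert totals["liver"][0] == pytest.approx(3.0 + 0.125 * 2.0)


class TestSimulate:
    def test_mass_conserved_without_clearance_and_release(self, mouse, mouse_bolus):
        rel = replace(mouse.released, CL=0.0)
        conj = replace(
            mouse.conjugated, krel_b=0.0, krel_L=0.0, krel_S=0.0, krel_R=0.0
        )
        course = nb.simulate(mouse.physiology, rel, conj, mouse_bolus)
        total = sum(course.states.values())
        np.testing.assert_allclose(total, 10.0, rtol=1e-6)

    def test_monotone_release_closed_form(self, mouse, mouse_bolus):
        # flows and CL zeroed: X_b decays exactly exp(-krel_b t), A_b -> X_b(0)
        ph = mouse.physiology
        rel = replace(mouse.released, CL=0.0, Q_BR=0.0)
        ph0 = replace(ph, Q_BL_i=1e-12, Q_BL_o=1e-12 + 1e-13, Q_BS=1e-13)
        conj = replace(mouse.conjugated, N_BL=0.0, N_BS=0.0, N_BR=0.0)
        t = np.linspace(0, 60, 61)
        course = nb.simulate(ph0, rel, conj, mouse_bolus, times=t)
        np.testing.assert_allclose(
            course.states["X_b"], 10.0 * np.exp(-conj.krel_b * t), rtol=1e-6
        )
        assert course.states["A_b"][-1] == pytest.approx(
            10.0 * (1 - np.exp(-conj.krel_b * 60)), rel=1e-6
        )

    def test_conjugated_subsystem_linear_in_dose(self, mouse):
        t = np.linspace(0, 48, 49)
        c1 = nb.simulate(mouse.physiology, mouse.released, mouse.conjugated,
                         nb.DoseRegimen(5.0, "bolus"), times=t)
        c2 = nb.simulate(mouse.physiology, mouse.released, mouse.conjugated,
                         nb.DoseRegimen(10.0, "bolus"), times=t)
        for key in ("X_b", "X_L", "X_S"):
            np.testing.assert_allclose(
                2.0 * c1.states[key], c2.states[key], rtol=1e-6, atol=1e-12
            )

    def test_total_at_least_released_everywhere(self, mouse_course):
        for matrix in ("plasma", "blood", "liver", "spleen"):
            tot = mouse_course.concentration(matrix, "total")
            rel = mouse_course.concentration(matrix, "released")
            assert np.all(tot >= rel - 1e-12)

    def test_tolerance_refinement_stable(self, mouse, mouse_bolus, mouse_course):
        fine = nb.simulate(mouse.physiology, mouse.released, mouse.conjugated,
                           mouse_bolus, rtol=1e-9, atol=1e-11)
        for key, series in mouse_course.concentrations.items():
            ref = fine.concentrations[key]
            mask = ref > 1e-12
            assert np.max(np.abs(series[mask] - ref[mask]) / ref[mask]) < 1e-3

    def test_infusion_conserves_dose_without_loss(self, rat):
        rel = replace(rat.released, CL=0.0)
        conj = replace(rat.conjugated, krel_b=0.0, krel_L=0.0, krel_S=0.0, krel_R=0.0)
        regimen = nb.DoseRegimen(55.0, "infusion", 0.5)
        t = np.array([0.0, 0.25, 0.5, 1.0, 24.0])
        course = nb.simulate(rat.physiology, rel, conj, regimen, times=t)
        total = sum(course.states.values())
        # half the dose in at mid-infusion, all of it after
        assert total[1] == pytest.approx(27.5, rel=1e-6)
        np.testing.assert_allclose(total[2:], 55.0, rtol=1e-6)

    def test_bad_time_grid_rejected(self, mouse, mouse_bolus):
        with pytest.raises(InvalidInputError):
            nb.simulate(mouse.physiology, mouse.released, mouse.conjugated,
                        mouse_bolus, times=np.array([0.0, 2.0, 1.0]))


class TestContainers:
    def test_physiology_flow_consistency_enforced(self, mouse):
        with pytest.raises(InvalidInputError):
            replace(mouse.physiology, Q_BL_i=5.0)

    def test_rest_volume_closes_unit_volume(self, human):
        assert rest_volume(human.physiology) == pytest.approx(0.8993, rel=1e-6)

    def test_regimen_validation(self):
        with pytest.raises(InvalidInputError):
            nb.DoseRegimen(-1.0, "bolus")
        with pytest.raises(InvalidInputError):
            nb.DoseRegimen(10.0, "infusion", 0.0)

    def test_tidy_frame_round_trip(self, mouse_course):
        frame = mouse_course.to_frame()
        assert set(frame["matrix"]) == {"plasma", "blood", "liver", "spleen"}
        assert set(frame["analyte"]) == {"released", "total"}
        assert (frame["concentration_ug_per_ml"] >= 0).all()
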