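"""Exergy and entropy-generation analyses."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gestex.exergy import (GIBBS_ADULT, GIBBS_FETAL, LUNG_AUX, PLACENTA_AUX,
                           GibbsTable, OrganAuxiliaries, ReferenceState,
                           blood_stream_exergy, hb_reaction_exergy,
                           lung_model1, lung_model3, placenta_model1,
                           stream_exergy)
from gestex.gases import CO, CO2, GASES, O2
from gestex.hemoglobin import ADULT, BloodState
from gestex.lung import LungResult
from gestex.placenta import PlacentaResult

REF = ReferenceState()


def _state(p_o2, p_co2, p_co, flow, t=310.15, s_o2=0.0, s_co=0.0,
           c=None):
    c = c or {"O2": 3e-5 * p_o2, "CO2": 0.0, "CO": 2.4e-5 * p_co}
    return BloodState(P={"O2": p_o2, "CO2": p_co2, "CO": p_co},
                      S={"O2": s_o2, "CO": s_co}, C=c, flow=flow, T=t)


class TestStreamExergy:
    @pytest.mark.parametrize("gas", [O2, CO2, CO])
    def test_zero_at_reference_state(self, gas):
        assert stream_exergy(gas, REF.T0, REF.P0, REF) == 0.0

    @given(t=st.floats(min_value=250.0, max_value=330.0))
    @settings(max_examples=100, deadline=None)
    def test_thermal_part_non_negative(self, t):
        """x - ln x convexity: the thermal term has its minimum at T0."""
        b = stream_exergy(O2, t, REF.P0, REF)
        assert b >= -1e-12

    def test_arterial_o2_hand_value(self):
        """cp(T - T0 - T0 ln(T/T0)) + R T0 ln(90/760), computed by hand."""
        assert stream_exergy(O2, 310.15, 90.0, REF) == pytest.approx(
            -165.07180983367726, rel=1e-12)

    def test_zero_pressure_is_domain_error(self):
        with pytest.raises(ValueError, match="zero partial pressure"):
            stream_exergy(O2, 310.15, 0.0, REF)


class TestGibbsTable:
    def test_fetal_table_values(self):
        assert GIBBS_FETAL.co == (-150.09, -301.04, -464.96, -634.09)
        assert GIBBS_FETAL.o2 == (-18.34, -37.41, -59.86, -95.89)

    def test_cooperativity_enforced(self):
        with pytest.raises(ValueError):
            GibbsTable(co=(-150.0, -140.0, -465.0, -634.0),
                       o2=(-18.0, -37.0, -60.0, -96.0))

    def test_adult_table_shifted_less_negative(self):
        """The adult stand-in is weaker-binding than fetal at every step."""
        for a, f in zip(GIBBS_ADULT.o2, GIBBS_FETAL.o2):
            assert a > f
        assert all(b < a for a, b in zip(GIBBS_ADULT.o2, GIBBS_ADULT.o2[1:]))


class TestHbReactionExergy:
    def test_full_loading_uses_cumulative_energy(self):
        """0 -> 4 site occupancy transfers 95.89 kJ per mol Hb (fetal O2);
        the unloading direction carries the opposite sign."""
        binding = hb_reaction_exergy(1.0, 0.0, 1.0, GIBBS_FETAL, "O2")
        assert binding == pytest.approx(95.89 * 1e3 / 60.0)
        unbinding = hb_reaction_exergy(1.0, 1.0, 0.0, GIBBS_FETAL, "O2")
        assert unbinding == pytest.approx(-95.89 * 1e3 / 60.0)

    def test_single_step_co_binding(self):
        """First CO site uses the first-step Gibbs energy, -150.09."""
        got = hb_reaction_exergy(1.0, 0.0, 0.25, GIBBS_FETAL, "CO")
        assert got == pytest.approx(150.09 * 1e3 / 60.0)

    def test_antisymmetric_under_state_swap(self):
        a = hb_reaction_exergy(2.0, 0.2, 0.8, GIBBS_FETAL, "O2")
        b = hb_reaction_exergy(2.0, 0.8, 0.2, GIBBS_FETAL, "O2")
        assert a == pytest.approx(-b)

    def test_additive_over_intermediate_states(self):
        whole = hb_reaction_exergy(1.0, 0.1, 0.9, GIBBS_ADULT, "O2")
        split = (hb_reaction_exergy(1.0, 0.1, 0.5, GIBBS_ADULT, "O2")
                 + hb_reaction_exergy(1.0, 0.5, 0.9, GIBBS_ADULT, "O2"))
        assert whole == pytest.approx(split)

    def test_zero_change_zero_exergy(self):
        assert hb_reaction_exergy(5.0, 0.4, 0.4, GIBBS_FETAL, "CO") == 0.0


def _reference_lung():
    """All streams at the dead state: every exergy term vanishes."""
    st_ref = _state(REF.P0, REF.P0, REF.P0, 1000.0, t=REF.T0,
                    c={"O2": 0.025, "CO2": 0.6, "CO": 0.02})
    p_ref = {"O2": REF.P0, "CO2": REF.P0, "CO": REF.P0}
    return LungResult(arterial=st_ref, venous=st_ref,
                      alveolar_pressures=dict(p_ref),
                      ventilation_stpd=5000.0,
                      inspired_pressures=dict(p_ref),
                      uptake={"O2": 0.0, "CO2": 0.0, "CO": 0.0},
                      dry_pressure=REF.P0)


class TestLungModels:
    def test_reference_state_destroys_nothing(self):
        """Dead-state streams and zero auxiliaries: B_d = 0, eta undefined."""
        aux0 = OrganAuxiliaries(B_M=0.0, Q_M=0.0, T_organ=310.15, W_resp=0.0)
        rep = lung_model1(_reference_lung(), aux0, REF, env_temperature=REF.T0)
        assert rep.B_d == pytest.approx(0.0, abs=1e-12)
        assert rep.eta is None
        assert any("undefined" in w for w in rep.warnings)

    def test_model3_zero_without_gradients(self):
        lung = _reference_lung()
        lung.uptake = {"O2": 100.0, "CO2": -80.0, "CO": 0.0}
        rep = lung_model3(lung, REF)  # P_ar == P_ex for every gas
        assert rep.sigma == pytest.approx(0.0, abs=1e-15)

    def test_model1_efficiency_flagged_outside_unit_interval(self,
                                                             baseline_lung):
        """Single-pressure reference exergies push eta past 1; the report
        carries the model-inconsistency warning instead of hiding it."""
        rep = lung_model1(baseline_lung)
        assert rep.eta is not None
        assert rep.warnings  # flagged, value still returned

    def test_model3_positive_under_exposure(self, lung_100ppm):
        rep = lung_model3(lung_100ppm)
        assert rep.sigma > 0
        assert rep.B_d == pytest.approx(REF.T0 * rep.sigma)
        assert all(v >= -1e-18 for v in rep.per_gas.values())


class TestPlacentaModels:
    def test_reference_state_destroys_nothing(self):
        st_ref = _state(REF.P0, REF.P0, REF.P0, 200.0, t=REF.T0,
                        c={"O2": 0.025, "CO2": 0.6, "CO": 0.02})
        plac = PlacentaResult(fetal_arterial=st_ref, fetal_venous=st_ref,
                              transfer={"O2": 0.0, "CO2": 0.0, "CO": 0.0},
                              residual={"O2": 0.0, "CO2": 0.0, "CO": 0.0})
        aux0 = OrganAuxiliaries(B_M=0.0, Q_M=0.0, T_organ=310.15)
        rep = placenta_model1(st_ref, st_ref, plac, aux0, REF)
        assert rep.B_d == pytest.approx(0.0, abs=1e-12)

    def test_sigma_non_negative_across_sweep(self, sweep_df):
        assert (sweep_df["sigma_plac_W_K"] >= 0).all()
        assert (sweep_df["sigma_lung_W_K"] >= 0).all()

    def test_placental_metabolism_dominates_efficiency(self, sweep_df):
        """CO exposure barely moves the Model 1 efficiency (high B_M)."""
        eta = sweep_df["eta_plac_m1"]
        assert eta.max() - eta.min() < 0.05


class TestAuxiliaries:
    def test_organ_warmer_than_reference(self):
        assert LUNG_AUX.T_organ > REF.T0
        assert PLACENTA_AUX.T_organ > REF.T0

    def test_heat_exergy_carnot_factor(self):
        aux = OrganAuxiliaries(B_M=1.0, Q_M=2.0, T_organ=310.15)
        assert aux.heat_exergy(REF) == pytest.approx(
            2.0 * (1.0 - 298.15 / 310.15))

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            OrganAuxiliaries(B_M=math.nan, Q_M=0.0, T_organ=310.15)
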