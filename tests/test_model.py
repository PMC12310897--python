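"""Unit tests of the equilibrium binding model: solubilities, Hill
coefficient, P50 shifts, saturations, species partitioning, pH conversion
and the bicarbonate nomogram."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hbcurve import (
    BloodGasState,
    ModelConstants,
    bicarbonate_nomogram,
    hill_coefficient,
    load_constants,
    p50,
    ph_plasma_from_rbc,
    ph_rbc_from_plasma,
    saturations,
    solubility_CO2,
    solubility_O2,
    species_distribution,
)

from conftest import random_states

C = ModelConstants()


class TestSolubilities:
    @pytest.mark.parametrize(
        "func, printed",
        [(solubility_O2, 1.46e-6), (solubility_CO2, 3.27e-5)],
        ids=["O2", "CO2"],
    )
    def test_printed_values_at_37C(self, func, printed):
        # printed reference values hold to 3 significant figures
        assert float(func(37.0)) == pytest.approx(printed, rel=5e-3)

    def test_plasma_water_correction_drops_out(self):
        c1 = ModelConstants(W_pl=1.0)
        assert float(solubility_O2(37.0, c1)) == pytest.approx(1.37e-6, abs=1e-20)
        assert float(solubility_CO2(37.0, c1)) == pytest.approx(3.07e-5, abs=1e-18)

    @pytest.mark.parametrize(
        "func, T, expected",
        [
            # hand evaluation of the temperature polynomials at +-1 degC
            (solubility_O2, 38.0, (1.37 - 1.37e-2 + 5.8e-4) * 1e-6 / 0.94),
            (solubility_CO2, 36.0, (3.07 + 5.7e-2 + 2e-3) * 1e-5 / 0.94),
        ],
        ids=["O2_38C", "CO2_36C"],
    )
    def test_hand_evaluated_polynomials(self, func, T, expected):
        assert float(func(T)) == pytest.approx(expected, rel=1e-12)

    def test_warns_outside_validity_range(self):
        with pytest.warns(UserWarning, match="solubility"):
            solubility_O2(25.0)


class TestHillCoefficient:
    def test_limits(self):
        assert float(hill_coefficient(0.0)) == pytest.approx(1.6, abs=1e-12)
        assert float(hill_coefficient(1e6)) == pytest.approx(2.8, abs=1e-12)

    def test_one_decade_point(self):
        # at PO2 = gamma the exponential term is exactly 10^-1
        assert float(hill_coefficient(29.2)) == pytest.approx(2.68, abs=1e-12)

    @given(st.floats(min_value=0.0, max_value=200.0), st.floats(min_value=0.01, max_value=50.0))
    @settings(max_examples=50, deadline=None)
    def test_strictly_increasing_and_bounded(self, po2, dpo2):
        lo, hi = float(hill_coefficient(po2)), float(hill_coefficient(po2 + dpo2))
        assert lo < hi
        assert C.hill_alpha - C.hill_beta <= lo < C.hill_alpha


class TestP50:
    def test_standard_state_is_26_8(self, standard_state):
        assert p50(standard_state) == pytest.approx(26.8, abs=1e-12)

    def test_temperature_shift_hand_value(self, standard_state):
        # only T deviates: Eq-by-hand 26.8 + 1.435 + 4.163e-2 + 6.86e-4
        st38 = standard_state.replace(T=38.0)
        assert p50(st38) == pytest.approx(26.8 + 1.435 + 4.163e-2 + 6.86e-4, rel=1e-12)

    def test_multiplicative_combination_of_two_shifts(self, standard_state):
        both = standard_state.replace(T=38.0, PCO2=50.0)
        only_T = p50(standard_state.replace(T=38.0))
        only_C = p50(standard_state.replace(PCO2=50.0))
        assert p50(both) == pytest.approx(26.8 * (only_T / 26.8) * (only_C / 26.8), rel=1e-12)

    def test_acidosis_raises_p50(self, standard_state):
        acidotic = standard_state.replace(pH_rbc=standard_state.pH_rbc - 0.2)
        assert p50(acidotic) > p50(standard_state)


class TestSaturations:
    def test_half_saturation_at_p50(self):
        for state in random_states(100, seed=11):
            at_p50 = state.replace(PO2=p50(state))
            assert saturations(at_p50).S_HbO2 == pytest.approx(0.5, abs=1e-10)

    def test_zero_po2_gives_zero_o2_saturation(self, standard_state):
        res = saturations(standard_state.replace(PO2=0.0))
        assert res.S_HbO2 == 0.0
        assert 0.0 < res.S_HbCO2 < 1.0

    def test_strictly_increasing_in_po2(self, standard_state):
        po2 = np.linspace(0.5, 100.0, 400)
        vals = [saturations(standard_state.replace(PO2=float(p))).S_HbO2 for p in po2]
        assert np.all(np.diff(vals) > 0)

    def test_bohr_direction(self, standard_state):
        base = standard_state.replace(PO2=40.0)
        acidotic = base.replace(pH_rbc=base.pH_rbc - 0.2)
        assert saturations(acidotic).S_HbO2 < saturations(base).S_HbO2

    def test_temperature_direction(self, standard_state):
        base = standard_state.replace(PO2=40.0)
        warm = base.replace(T=38.0)
        assert saturations(warm).S_HbO2 < saturations(base).S_HbO2

    def test_invariant_to_hct_and_hb(self):
        for state in random_states(50, seed=7):
            ref = saturations(state)
            for hct in (0.2, 0.45, 0.6):
                for hb in (0.004, 0.00528, 0.006):
                    alt = saturations(state.replace(Hct=hct, Hb_rbc=hb))
                    assert alt.S_HbO2 == ref.S_HbO2
                    assert alt.S_HbCO2 == ref.S_HbCO2

    def test_nh_within_hill_bounds(self, standard_state):
        res = saturations(standard_state.replace(PO2=30.0))
        assert C.hill_alpha - C.hill_beta < res.nH < C.hill_alpha

    def test_rejects_negative_po2(self, standard_state):
        with pytest.raises(ValueError):
            BloodGasState(PO2=-1.0, PCO2=40.0, pH_rbc=7.24)


class TestSpeciesDistribution:
    def test_fractions_sum_to_one_and_match_saturations(self):
        for state in random_states(100, seed=3):
            sp = species_distribution(state)
            sat = saturations(state)
            assert float(np.sum(sp.fractions)) == pytest.approx(1.0, abs=1e-12)
            oxy = sp.f_O2HbNH2 + sp.f_O2HbNH3p + sp.f_O2HbNHCOOH + sp.f_O2HbNHCOOm
            carb = sp.f_HbNHCOOH + sp.f_HbNHCOOm + sp.f_O2HbNHCOOH + sp.f_O2HbNHCOOm
            assert oxy == pytest.approx(sat.S_HbO2, abs=1e-10)
            assert carb == pytest.approx(sat.S_HbCO2, abs=1e-8)

    def test_carbamate_vanishes_without_co2(self, standard_state):
        sp = species_distribution(standard_state.replace(PCO2=1e-6))
        for f in (sp.f_HbNHCOOH, sp.f_HbNHCOOm, sp.f_O2HbNHCOOH, sp.f_O2HbNHCOOm):
            assert f < 1e-6

    def test_absolute_concentrations_scale(self, standard_state):
        sp = species_distribution(standard_state)
        conc = sp.concentrations(Hb_rbc=0.00528, Hct=0.45)
        assert float(np.sum(conc)) == pytest.approx(4 * 0.00528 * 0.45, rel=1e-12)


class TestPhConversion:
    def test_gibbs_donnan_shift(self):
        assert float(ph_rbc_from_plasma(7.40)) == pytest.approx(7.40 + np.log10(0.69), abs=1e-12)

    @given(st.floats(min_value=6.5, max_value=7.8))
    @settings(max_examples=50, deadline=None)
    def test_round_trip_identity(self, ph):
        assert float(ph_plasma_from_rbc(ph_rbc_from_plasma(ph))) == pytest.approx(ph, abs=1e-12)

    def test_unit_donnan_ratio_is_identity(self):
        c = ModelConstants(gibbs_donnan=1.0)
        assert float(ph_rbc_from_plasma(7.3, c)) == 7.3


class TestBicarbonateNomogram:
    def test_hand_evaluated_reference_point(self):
        expo = 7.4 - 7.376 * (1 - 0.00305 * 15) + 0.848 * (1 - 0.0162 * 15) * np.log10(40)
        assert float(bicarbonate_nomogram(7.4, 40.0, 15.0)) == pytest.approx(10**expo, rel=1e-12)

    def test_zero_hb_reduction(self):
        expo = 7.3 - 7.376 + 0.848 * np.log10(50.0)
        assert float(bicarbonate_nomogram(7.3, 50.0, 0.0)) == pytest.approx(10**expo, rel=1e-12)

    def test_monotone_in_ph(self):
        ph = np.linspace(6.9, 7.6, 30)
        vals = bicarbonate_nomogram(ph, 40.0, 15.0)
        assert np.all(np.diff(vals) > 0)

    def test_rejects_nonpositive_pco2(self):
        with pytest.raises(ValueError):
            bicarbonate_nomogram(7.4, 0.0, 15.0)


class TestConstantsConfig:
    def test_defaults_are_valid_and_frozen(self):
        c = ModelConstants()
        with pytest.raises(dataclasses.FrozenInstanceError):
            c.P50_S = 30.0

    def test_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            ModelConstants(K2p=0.0)
        with pytest.raises(ValueError):
            ModelConstants(W_pl=1.5)

    def test_load_from_yaml_and_overrides(self, tmp_path):
        path = tmp_path / "constants.yaml"
        path.write_text("P50_S: 27.5\nW_pl: 0.9\n")
        c = load_constants(path)
        assert c.P50_S == 27.5 and c.W_pl == 0.9 and c.K2p == 21.5
        c2 = load_constants(path, P50_S=28.0)
        assert c2.P50_S == 28.0

    def test_load_rejects_unknown_keys(self, tmp_path):
        path = tmp_path / "constants.yaml"
        path.write_text("nonsense: 1\n")
        with pytest.raises(KeyError):
            load_constants(path)
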