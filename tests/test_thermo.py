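"""In-situ Gibbs energies, activity coefficients and reaction bookkeeping."""

import math

import numpy as np
import pytest

from hotbio import thermo
from hotbio.units import R_KJ


@pytest.fixture(scope="module")
def dh():
    return thermo.load_dh_params()


@pytest.fixture(scope="module")
def reactions():
    return thermo.load_reactions()


class TestTemperatureModel:
    def test_surface(self):
        assert thermo.insitu_temperature(0.0) == pytest.approx(2.0)

    def test_linear_evaluation(self):
        # 100 degC/km from 2 degC: 920 mbsf -> 94 degC
        assert thermo.insitu_temperature(920.0, 100.0, 2.0) == pytest.approx(94.0)
        # 110 degC/km: ~120 degC near the basement
        assert thermo.insitu_temperature(1073.0, 110.0, 2.0) == pytest.approx(120.0, abs=1.0)

    def test_negative_depth_rejected(self):
        with pytest.raises(ValueError):
            thermo.insitu_temperature(-1.0)


class TestActivityCoefficient:
    def test_infinite_dilution_unity(self, dh):
        state = thermo.ThermoState(temperature=298.15, ionic_strength=0.0)
        for charge, bdot in [(-2, None), (0, None), (1, 0.0)]:
            sp = thermo.Species("X", charge, 1e-3, 4.0, bdot)
            assert thermo.activity_coefficient(sp, state, dh) == pytest.approx(1.0)

    def test_neutral_species_with_zero_bdot(self, dh):
        state = thermo.ThermoState(temperature=298.15, ionic_strength=0.64)
        sp = thermo.Species("X", 0, 1e-3, 0.0, bdot=0.0)
        assert thermo.activity_coefficient(sp, state, dh) == pytest.approx(1.0)

    def test_closed_form_at_25C(self, dh):
        # divalent anion, a0 = 4 A, bdot = 0, I = 0.64, 25 degC table values
        state = thermo.ThermoState(temperature=298.15, ionic_strength=0.64)
        sp = thermo.Species("SO4--", -2, 1e-2, 4.0, bdot=0.0)
        A, B = 0.5092, 0.3283
        expected = 10 ** (-A * 4 * math.sqrt(0.64) / (1 + B * 4.0 * math.sqrt(0.64)))
        assert thermo.activity_coefficient(sp, state, dh) == pytest.approx(expected, rel=1e-9)

    def test_gamma_monotone_to_unity_as_I_vanishes(self, dh):
        sp = thermo.Species("X", -1, 1e-3, 4.0, bdot=0.0)
        gammas = [
            thermo.activity_coefficient(
                sp, thermo.ThermoState(temperature=298.15, ionic_strength=i), dh
            )
            for i in (0.64, 0.3, 0.1, 0.01, 0.0)
        ]
        assert all(g2 > g1 for g1, g2 in zip(gammas, gammas[1:]))
        assert gammas[-1] == pytest.approx(1.0)

    def test_temperature_outside_table_rejected(self, dh):
        sp = thermo.Species("X", -1, 1e-3)
        with pytest.raises(ValueError):
            thermo.activity_coefficient(
                sp, thermo.ThermoState(temperature=500.0, ionic_strength=0.64), dh
            )

    def test_below_detection_floor_applied(self):
        sp = thermo.Species("HS-", -1, 0.0, below_detection=True)
        assert sp.effective_concentration() == pytest.approx(1e-7)


class TestActivityQuotient:
    def test_unit_activities(self, reactions):
        assert thermo.activity_quotient(reactions["AOM"], {
            "CH4": 1.0, "SO4--": 1.0, "HCO3-": 1.0, "HS-": 1.0,
        }) == pytest.approx(1.0)

    def test_hand_product(self, reactions):
        # (1e-3 * 1e-7) / (1e-3 * 1e-2) = 1e-5
        q = thermo.activity_quotient(reactions["AOM"], {
            "CH4": 1e-3, "SO4--": 1e-2, "HCO3-": 1e-3, "HS-": 1e-7,
        })
        assert q == pytest.approx(1e-5)

    def test_doubling_a_unit_reactant_halves_q(self, reactions):
        act = {"CH4": 1e-3, "SO4--": 1e-2, "HCO3-": 1e-3, "HS-": 1e-7}
        q1 = thermo.activity_quotient(reactions["AOM"], act)
        act["CH4"] *= 2
        assert thermo.activity_quotient(reactions["AOM"], act) == pytest.approx(q1 / 2)

    def test_zero_product_activity_gives_zero_q(self, reactions):
        q = thermo.activity_quotient(reactions["AOM"], {
            "CH4": 1e-3, "SO4--": 1e-2, "HCO3-": 0.0, "HS-": 1e-7,
        })
        assert q == 0.0

    def test_zero_reactant_activity_undefined(self, reactions):
        with pytest.raises(ZeroDivisionError):
            thermo.activity_quotient(reactions["AOM"], {
                "CH4": 0.0, "SO4--": 1e-2, "HCO3-": 1e-3, "HS-": 1e-7,
            })

    def test_missing_activity_rejected(self, reactions):
        with pytest.raises(KeyError):
            thermo.activity_quotient(reactions["AOM"], {"CH4": 1e-3})


class TestGibbsEnergy:
    def test_q_of_one_returns_standard_state(self):
        rxn = thermo.ReactionSpec("r", {"CH4": 1}, -50.0)
        state = thermo.ThermoState(temperature=373.15)
        assert thermo.gibbs_energy(rxn, state, 1.0) == pytest.approx(-50.0)

    def test_rt_ln_term(self):
        # RT ln 10 at 373.15 K = 0.008314 * 373.15 * ln 10 ~ 7.14 kJ/mol
        rxn = thermo.ReactionSpec("r", {"CH4": 1}, 0.0)
        state = thermo.ThermoState(temperature=373.15)
        assert thermo.gibbs_energy(rxn, state, 10.0) == pytest.approx(
            0.008314 * 373.15 * math.log(10), rel=1e-9
        )

    def test_nonpositive_q_rejected(self):
        rxn = thermo.ReactionSpec("r", {"CH4": 1}, 0.0)
        state = thermo.ThermoState(temperature=373.15)
        for q in (0.0, -1.0):
            with pytest.raises(ValueError):
                thermo.gibbs_energy(rxn, state, q)

    def test_slope_in_ln_q_is_rt(self):
        rxn = thermo.ReactionSpec("r", {"CH4": 1}, -10.0)
        state = thermo.ThermoState(temperature=350.0)
        lnq = np.linspace(-5, 5, 11)
        dg = np.array([thermo.gibbs_energy(rxn, state, math.exp(x)) for x in lnq])
        slopes = np.diff(dg) / np.diff(lnq)
        assert slopes == pytest.approx(R_KJ * 350.0, rel=1e-9)

    def test_reversal_negates_ln_q_and_flips_sign(self, reactions):
        rxn = reactions["SR_acetate"]
        act = {"SO4--": 1e-2, "CH3COO-": 5e-3, "HS-": 1e-7, "HCO3-": 1e-4}
        state = thermo.ThermoState(temperature=373.15)
        q_fwd = thermo.activity_quotient(rxn, act)
        q_rev = thermo.activity_quotient(rxn.reversed(), act)
        assert math.log(q_rev) == pytest.approx(-math.log(q_fwd), rel=1e-9)
        dg_fwd = thermo.gibbs_energy(rxn, state, q_fwd)
        dg_rev = thermo.gibbs_energy(rxn.reversed(), state, q_rev)
        assert dg_rev - rxn.reversed().dG0_insitu == pytest.approx(
            -(dg_fwd - rxn.dG0_insitu), rel=1e-9
        )


def test_all_packaged_reactions_balanced(reactions):
    assert len(reactions) == 5
    for name, rxn in reactions.items():
        assert thermo.reaction_balance(rxn) == {}, name


def test_reference_state_reproduces_published_energy_yields(reactions, dh):
    """The packaged deep-sediment fixture gives ~-105 kJ/mol SO4 for
    acetotrophic sulfate reduction and ~-43 kJ/mol CH4 for acetotrophic
    methanogenesis at 920 mbsf / 100 degC."""
    ref = thermo.load_reference_state()
    state = thermo.ThermoState(
        temperature=ref["temperature_C"] + 273.15,
        pressure=ref["pressure_MPa"],
        ionic_strength=ref["ionic_strength"],
    )
    species = thermo.build_species(
        ref["concentrations_mol_l"], {n: True for n in ref["below_detection"]}
    )
    act = thermo.activities(species, state, dh, ph=ref["ph"])
    dg_sr = thermo.gibbs_energy(
        reactions["SR_acetate"], state,
        thermo.activity_quotient(reactions["SR_acetate"], act),
    )
    dg_mg = thermo.gibbs_energy(
        reactions["MG_acetate"], state,
        thermo.activity_quotient(reactions["MG_acetate"], act),
    )
    assert dg_sr == pytest.approx(-105.0, abs=0.5)
    assert dg_mg == pytest.approx(-43.0, abs=0.5)
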