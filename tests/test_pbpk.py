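"""Compartmental model: clearance scaling, dynamics, conservation, oracle."""

import numpy as np
import pytest

from neuropbpk.errors import InvalidInputError
from neuropbpk.neuropk import InVitroPermeability
from neuropbpk.pbpk import (
    DoseKind,
    DosingMode,
    DrugParams,
    ScalingFactors,
    StateVector,
    administered,
    analytic_solution,
    build_clearances,
    infer_dosing,
    rhs,
    simulate,
    total_in_system,
)
from neuropbpk.physiology import DEFAULT_PHYSIOLOGY, Physiology


def _random_setup(rng):
    drug = DrugParams(
        name="rnd",
        fu_plasma=rng.uniform(0.05, 1.0),
        v_d=rng.uniform(100, 5000),
        k_el=10 ** rng.uniform(-5, -3.5),
        k_a=10 ** rng.uniform(-4.5, -3) if rng.random() < 0.5 else None,
        dose=rng.uniform(1e5, 5e6),
        k_0=None,
        rat_weight=250.0,
    )
    perm = InVitroPermeability(
        papp_ab=10 ** rng.uniform(-5.5, -3.5),
        papp_ba=10 ** rng.uniform(-5.5, -3.5),
        fu_brain=rng.uniform(0.03, 1.0),
    )
    sc = ScalingFactors(
        sc1=10 ** rng.uniform(-1, 3),
        sc2=10 ** rng.uniform(-1, 3),
        sc3=10 ** rng.uniform(-2, 1),
    )
    return drug, perm, sc


class TestClearances:
    def test_direct_product(self):
        perm = InVitroPermeability(papp_ab=1e-6, papp_ba=1e-6, fu_brain=1.0)
        c = build_clearances(perm, ScalingFactors())
        assert c.ps_bbb_in == pytest.approx(1.875e-4)

    def test_surface_ratio_is_invariant(self):
        perm = InVitroPermeability(papp_ab=7e-6, papp_ba=3e-6, fu_brain=0.5)
        c = build_clearances(perm, ScalingFactors(2.0, 5.0, 1.0))
        assert c.ps_bbb_in / c.ps_bcsfb_in == pytest.approx(187.5 / 0.0375)
        assert c.ps_bbb_out / c.ps_bcsfb_out == pytest.approx(5000.0)

    def test_carbamazepine_mdck_fixture(self, perm_table, fitted_tables):
        c = build_clearances(
            perm_table[("carbamazepine", "MDCK")],
            fitted_tables[1][("carbamazepine", "MDCK")],
        )
        assert c.ps_bbb_in == pytest.approx(0.5527, abs=2e-4)


class TestDosingInference:
    def test_bolus_when_dose_only(self, drug_table):
        assert infer_dosing(drug_table["zolpidem"]).kind == DoseKind.IV_BOLUS

    def test_infusion_duration_from_dose_over_rate(self, drug_table):
        mode = infer_dosing(drug_table["pefloxacin"])
        assert mode.kind == DoseKind.IV_INFUSION
        assert mode.infusion_duration == pytest.approx(17136, rel=1e-4)

    def test_open_ended_infusion_when_no_dose(self, drug_table):
        mode = infer_dosing(drug_table["caffeine"])
        assert mode.kind == DoseKind.IV_INFUSION
        assert mode.infusion_duration is None

    def test_extravascular_when_ka_and_dose(self, drug_table):
        assert (infer_dosing(drug_table["amitriptyline"]).kind
                == DoseKind.EXTRAVASCULAR)


class TestRHS:
    def setup_method(self):
        self.drug = DrugParams(name="d", fu_plasma=0.5, v_d=1000.0,
                               k_el=1e-4, dose=1e6)
        self.perm = InVitroPermeability(papp_ab=5e-6, papp_ba=8e-6,
                                        fu_brain=0.4)
        self.clear = build_clearances(self.perm, ScalingFactors(2, 3, 1))

    def test_origin_is_equilibrium(self):
        dy = rhs(np.zeros(5), self.drug, self.clear, 1.0, 0.4,
                 DEFAULT_PHYSIOLOGY, DosingMode(DoseKind.IV_BOLUS))
        assert np.all(dy == 0)

    def test_amount_rates_conserve_mass(self):
        rng = np.random.default_rng(7)
        phys = DEFAULT_PHYSIOLOGY
        for _ in range(10):
            y = rng.uniform(0, 100, size=5)
            dy = rhs(y, self.drug, self.clear, 1.3, 0.4, phys,
                     DosingMode(DoseKind.IV_BOLUS))
            total_rate = (dy[0] + dy[1] * self.drug.v_d + dy[2] * phys.v_b
                          + dy[3] * phys.v_csf + dy[4])
            assert total_rate == pytest.approx(0.0, abs=1e-9 * np.abs(y).max())

    def test_infusion_source_appears_in_balance(self):
        drug = DrugParams(name="d", fu_plasma=0.5, v_d=1000.0, k_el=1e-4,
                          k_0=500.0)
        phys = DEFAULT_PHYSIOLOGY
        dy = rhs(np.zeros(5), drug, self.clear, 1.0, 0.4, phys,
                 DosingMode(DoseKind.IV_INFUSION), t=0.0)
        assert dy[1] * drug.v_d == pytest.approx(500.0)

    def test_reduces_to_one_compartment_when_decoupled(self):
        # vanishing barrier transport: plasma decays with k_el alone
        perm = InVitroPermeability(papp_ab=1e-300, papp_ba=1e-300,
                                   fu_brain=1.0)
        clear = build_clearances(perm, ScalingFactors())
        phys = Physiology(q_bulk=1e-300, q_sink=1e-300)
        y = np.array([0.0, 50.0, 0.0, 0.0, 0.0])
        dy = rhs(y, self.drug, clear, 1.0, 1.0, phys,
                 DosingMode(DoseKind.IV_BOLUS))
        assert dy[1] == pytest.approx(-self.drug.k_el * 50.0, rel=1e-9)


class TestSimulate:
    def test_decoupled_bolus_is_monoexponential(self):
        drug = DrugParams(name="d", fu_plasma=0.5, v_d=500.0, k_el=1e-4,
                          dose=1e6)
        perm = InVitroPermeability(papp_ab=1e-300, papp_ba=1e-300,
                                   fu_brain=1.0)
        phys = Physiology(q_bulk=1e-300, q_sink=1e-300)
        t = np.linspace(0, 5 * np.log(2) / drug.k_el, 60)
        prof = simulate(drug, perm, ScalingFactors(), phys,
                        DosingMode(DoseKind.IV_BOLUS), t)
        expected = drug.dose / drug.v_d * np.exp(-drug.k_el * t)
        np.testing.assert_allclose(prof[("plasma", "total")].values,
                                   expected, rtol=1e-6)

    def test_plasma_auc_to_infinity_equals_dose_over_clearance(
        self, fitted_drugs, perm_table, fitted_tables
    ):
        # elimination only occurs from plasma, so mass balance forces
        # AUC(0->inf) = D / (k_el * V_d) whatever the brain kinetics are
        drug = fitted_drugs["zolpidem"]
        perm = perm_table[("zolpidem", "MDCK")]
        sc = fitted_tables[1][("zolpidem", "MDCK")]
        t_end = 12 * np.log(2) / drug.k_el
        t = np.linspace(0, t_end, 4001)
        prof, states = simulate(drug, perm, sc, times=t, method="analytic",
                                return_states=True)
        auc = np.trapezoid(prof[("plasma", "total")].values, t)
        remaining = (drug.dose - states[-1, 4]) / (drug.k_el * drug.v_d)
        expected = drug.dose / (drug.k_el * drug.v_d)
        assert auc + remaining == pytest.approx(expected, rel=1e-3)

    def test_caffeine_infusion_steady_state(self, fitted_drugs, perm_table,
                                            fitted_tables):
        drug = fitted_drugs["caffeine"]
        expected = drug.k_0 / (drug.k_el * drug.v_d)
        assert expected == pytest.approx(85797, rel=1e-4)
        t = np.linspace(0, 40 / drug.k_el, 301)  # deep into steady state
        prof = simulate(drug, perm_table[("caffeine", "MDCK")],
                        fitted_tables[1][("caffeine", "MDCK")], times=t,
                        method="analytic")
        assert prof[("plasma", "total")].values[-1] == pytest.approx(
            expected, rel=1e-3
        )

    def test_linearity_in_dose(self, fitted_drugs, perm_table, fitted_tables):
        import dataclasses

        drug = fitted_drugs["zolpidem"]
        perm = perm_table[("zolpidem", "MDCK")]
        sc = fitted_tables[1][("zolpidem", "MDCK")]
        t = np.linspace(0, 3e4, 40)
        p1 = simulate(drug, perm, sc, times=t, method="analytic")
        p2 = simulate(dataclasses.replace(drug, dose=2 * drug.dose),
                      perm, sc, times=t, method="analytic")
        for key in p1:
            np.testing.assert_allclose(p2[key].values, 2 * p1[key].values,
                                       rtol=1e-10)

    def test_steady_state_brain_plasma_ratio_under_infusion(self):
        # at stationarity the brain balance gives
        # C_u,b / C_u,p = PS_bbb_in / (PS_bbb_out + Q_bulk)
        drug = DrugParams(name="d", fu_plasma=0.6, v_d=400.0, k_el=5e-5,
                          k_0=1000.0)
        perm = InVitroPermeability(papp_ab=3e-5, papp_ba=5e-5, fu_brain=0.3)
        sc = ScalingFactors(4.0, 2.0, 0.8)
        phys = DEFAULT_PHYSIOLOGY
        clear = build_clearances(perm, sc, phys)
        t = np.linspace(0, 60 / drug.k_el, 121)
        prof = simulate(drug, perm, sc, phys, times=t, method="analytic")
        cub = prof[("brain", "unbound")].values[-1]
        cup = prof[("plasma", "unbound")].values[-1]
        expected = clear.ps_bbb_in / (clear.ps_bbb_out + phys.q_bulk)
        # Q_bulk enters with the unbound brain concentration, so the exact
        # balance is PSin*Cup = (PSout + Qbulk)*Cub
        assert cub / cup == pytest.approx(expected, rel=1e-6)

    def test_unknown_dosing_kind_rejected(self):
        drug = DrugParams(name="d", fu_plasma=0.5, v_d=500.0, k_el=1e-4,
                          dose=1e6)
        perm = InVitroPermeability(papp_ab=1e-6, papp_ba=1e-6, fu_brain=1.0)
        with pytest.raises(InvalidInputError):
            simulate(drug, perm, ScalingFactors(),
                     dosing=DosingMode("intrathecal"), times=[0.0, 10.0])


class TestMassConservation:
    @pytest.mark.parametrize("drug_name", ["zolpidem", "pefloxacin",
                                           "caffeine", "amitriptyline"])
    def test_closed_system_every_mode(self, drug_name, fitted_drugs,
                                      perm_table, fitted_tables):
        drug = fitted_drugs[drug_name]
        perm = perm_table[(drug_name, "MDCK")]
        sc = fitted_tables[1][(drug_name, "MDCK")]
        dosing = infer_dosing(drug)
        t = np.linspace(0, 5 * np.log(2) / drug.k_el, 80)
        _, states = simulate(drug, perm, sc, dosing=dosing, times=t,
                             return_states=True)
        total = total_in_system(states, drug, DEFAULT_PHYSIOLOGY)
        given = administered(drug, dosing, t)
        scale = drug.dose if drug.dose is not None else given[-1]
        np.testing.assert_allclose(total, given, atol=1e-6 * scale)

    def test_nonnegative_states(self, fitted_drugs, perm_table, fitted_tables):
        for key in [("amitriptyline", "MDCK-MDR1"), ("caffeine", "hCMEC")]:
            drug = fitted_drugs[key[0]]
            t = np.linspace(0, 5 * np.log(2) / drug.k_el, 80)
            _, states = simulate(drug, perm_table[key], fitted_tables[1][key],
                                 times=t, return_states=True)
            assert states.min() >= -1e-9 * states.max()


class TestAnalyticOracle:
    def test_initial_state_exact(self, fitted_drugs, perm_table,
                                 fitted_tables):
        drug = fitted_drugs["zolpidem"]
        s = analytic_solution(drug, perm_table[("zolpidem", "MDCK")],
                              fitted_tables[1][("zolpidem", "MDCK")], t=0.0)
        assert s.c_p == pytest.approx(drug.dose / drug.v_d)
        assert s.c_b == s.c_csf == s.a_eliminated == 0.0

    def test_matches_solver_on_random_parameter_sets(self):
        rng = np.random.default_rng(42)
        for _ in range(20):
            drug, perm, sc = _random_setup(rng)
            dosing = infer_dosing(drug)
            t = np.linspace(0, 5 * np.log(2) / drug.k_el, 25)
            _, a = simulate(drug, perm, sc, dosing=dosing, times=t,
                            return_states=True)
            _, b = simulate(drug, perm, sc, dosing=dosing, times=t,
                            method="analytic", return_states=True)
            err = np.abs(a - b) / (np.abs(b).max(axis=0) + 1e-300)
            assert err.max() < 1e-6

    def test_infusion_switch_is_continuous(self, fitted_drugs, perm_table,
                                           fitted_tables):
        drug = fitted_drugs["pefloxacin"]
        dosing = infer_dosing(drug)
        t_inf = dosing.infusion_duration
        key = ("pefloxacin", "MDCK")
        eps = 1e-3
        lo = analytic_solution(fitted_drugs["pefloxacin"], perm_table[key],
                               fitted_tables[1][key], dosing=dosing,
                               t=t_inf - eps)
        hi = analytic_solution(fitted_drugs["pefloxacin"], perm_table[key],
                               fitted_tables[1][key], dosing=dosing,
                               t=t_inf + eps)
        assert hi.c_p == pytest.approx(lo.c_p, rel=1e-5)


def test_state_vector_round_trip():
    s = StateVector(1.0, 2.0, 3.0, 4.0, 5.0)
    assert StateVector.from_array(s.to_array()) == s
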