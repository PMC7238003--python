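import numpy as np
import pytest

import segflow as sf
from segflow import engine

from conftest import random_bundle


def _grid(t_end=48.0, n=97):
    return np.linspace(0.0, t_end, n)


class TestBuildModel:
    def test_column_conservation(self, worked):
        model = sf.build_model(*worked)
        colsum = model.A.sum(axis=0)
        assert np.abs(colsum).max() < 1e-12 * np.abs(model.A).max()

    def test_offdiagonals_nonnegative(self, worked):
        model = sf.build_model(*worked)
        off = model.A - np.diag(np.diag(model.A))
        assert (off >= 0).all()

    def test_tm_limit_leaves_serosa_flowless(self, worked):
        drug, phys, _ = worked
        model = sf.build_model(drug, phys, sf.FlowModelSpec(variant="TM"))
        i = model.index("ser")
        assert np.all(model.A[i, :] == 0) and np.all(model.A[:, i] == 0)

    def test_unknown_variant_rejected(self, worked):
        drug, phys, _ = worked
        with pytest.raises(ValueError, match="ssfm"):
            sf.build_model(
                drug, phys, sf.FlowModelSpec(variant="SSFM", n_segments=3)
            )


class TestSimulate:
    def test_iv_with_no_clearance_conserves_central_mass_flow(self):
        drug = sf.DrugParams(cl_d1_i=1, cl_d2_i=1, cl_d1_h=1, cl_d2_h=1)
        phys = sf.Physiology()
        model = sf.build_model(drug, phys, sf.FlowModelSpec(variant="SFM"))
        sim = sf.simulate(model, [sf.DoseEvent(route="iv", amount=2.0)], _grid())
        total = sim.amounts.sum(axis=1)
        assert np.allclose(total, 2.0, rtol=1e-10)

    def test_po_fully_absorbed_reaches_central(self):
        drug = sf.DrugParams(f_a=1.0, k_a=2.0, cl_d1_i=1, cl_d2_i=1,
                             cl_d1_h=1, cl_d2_h=1)
        phys = sf.Physiology()
        model = sf.build_model(drug, phys, sf.FlowModelSpec(variant="SFM"))
        sim = sf.simulate(
            model, [sf.DoseEvent(route="po", amount=1.0)], _grid(400.0, 11)
        )
        assert sim.amount("central")[-1] == pytest.approx(
            1.0 * phys.v_b / (phys.v_b + phys.v_eb + phys.v_ec + phys.v_ser
                              + phys.v_lb + phys.v_lc), rel=0.2
        )
        # everything eventually distributes out of the lumen
        assert sim.amount("lumen")[-1] < 1e-12

    def test_mass_balance_across_random_models_and_routes(self):
        rng = np.random.default_rng(11)
        for _ in range(10):
            bundle = random_bundle(rng)
            model = sf.build_model(*bundle)
            for route in ("po", "iv"):
                sim = sf.simulate(
                    model, [sf.DoseEvent(route=route, amount=3.0)], _grid()
                )
                assert sim.mass_balance_error() < 1e-8

    def test_dose_route_without_mapping_rejected(self, worked):
        model = sf.build_model(*worked)
        dose = sf.DoseEvent(route="po", amount=1.0)
        object.__setattr__(dose, "route", "sc")
        with pytest.raises(ValueError, match="route"):
            sf.simulate(model, [dose], _grid())

    def test_non_monotone_grid_rejected(self, worked):
        model = sf.build_model(*worked)
        with pytest.raises(ValueError, match="t_grid"):
            sf.simulate(model, [sf.DoseEvent(route="iv", amount=1.0)],
                        [0.0, 2.0, 1.0])


class TestAUC:
    def test_renal_only_elimination_gives_dose_over_clearance(self):
        drug = sf.DrugParams(cl_d1_i=1, cl_d2_i=1, cl_d1_h=1, cl_d2_h=1, cl_r=0.5)
        phys = sf.Physiology()
        model = sf.build_model(drug, phys, sf.FlowModelSpec(variant="SFM"))
        auc = sf.auc_to_infinity(model, [sf.DoseEvent(route="iv", amount=2.0)])
        assert auc[model.index("central")] / phys.v_b == pytest.approx(
            2.0 / 0.5, rel=1e-10
        )

    def test_linear_solve_agrees_with_trapezoid_plus_tail(self, worked):
        model = sf.build_model(*worked)
        dose = [sf.DoseEvent(route="po", amount=1.0)]
        grid = np.linspace(0.0, 200.0, 4001)
        sim = sf.simulate(model, dose, grid)
        exact = sf.auc_to_infinity(model, dose)
        i = model.index("central")
        # tail beyond the grid from the exact remaining-amount solve
        tail = np.linalg.solve(model.a_dyn, -sim.amounts[-1, : model.n_dyn])
        numeric = sim.auc_last[i] + tail[i]
        assert numeric == pytest.approx(exact[i], rel=1e-3)

    def test_dose_linearity(self, worked):
        model = sf.build_model(*worked)
        a1 = sf.auc_to_infinity(model, [sf.DoseEvent(route="po", amount=1.0)])
        a2 = sf.auc_to_infinity(model, [sf.DoseEvent(route="po", amount=2.0)])
        assert np.allclose(a2, 2.0 * a1, rtol=1e-12)

    def test_trapped_drug_is_an_explicit_error(self):
        drug = sf.DrugParams(cl_d1_i=1, cl_d2_i=1, cl_d1_h=1, cl_d2_h=1)
        model = sf.build_model(
            drug, sf.Physiology(), sf.FlowModelSpec(variant="SFM")
        )
        with pytest.raises(np.linalg.LinAlgError, match="trapped|singular"):
            sf.auc_to_infinity(model, [sf.DoseEvent(route="iv", amount=1.0)])

    def test_sink_totals_account_for_the_whole_dose(self, worked):
        model = sf.build_model(*worked)
        for route in ("po", "iv"):
            sinks = sf.sink_totals_to_infinity(
                model, [sf.DoseEvent(route=route, amount=1.0)]
            )
            assert sinks.sum() == pytest.approx(1.0, abs=1e-10)
            assert (sinks >= -1e-15).all()


class TestOracleEquivalence:
    def test_simulated_fsys_matches_closed_form_worked_example(self, worked):
        model = sf.build_model(*worked)
        fs = sf.fsys_from_sim(model)
        # hand value: 0.8 * (0.075/0.3545) * (2.5/3.5) = 0.1208946...
        assert fs["f_sys"] == pytest.approx(0.8 * (0.075 / 0.3545) * (2.5 / 3.5),
                                            rel=1e-9)

    def test_simulated_fsys_matches_closed_form_random_draws(self):
        rng = np.random.default_rng(123)
        for _ in range(100):
            drug, phys, spec = random_bundle(rng)
            av = sf.availability(drug, phys, spec)
            fs = sf.fsys_from_sim(sf.build_model(drug, phys, spec))
            assert fs["f_sys"] == pytest.approx(av.f_sys, rel=5e-3)
            assert fs["f_i_po"] == pytest.approx(av.f_i, rel=1e-9)
            assert 1 - fs["f_i_iv"] == pytest.approx(av.e_i_circ, rel=1e-9, abs=1e-12)
            assert fs["f_h_first_pass"] == pytest.approx(av.f_h, rel=1e-9)

    def test_tm_reduction_in_the_ode_engine(self, worked):
        drug, phys, _ = worked
        tm = sf.fsys_from_sim(
            sf.build_model(drug, phys, sf.FlowModelSpec(variant="TM"))
        )
        sfm1 = sf.fsys_from_sim(
            sf.build_model(drug, phys, sf.FlowModelSpec(variant="SFM", f_q=1.0))
        )
        for key in ("f_sys", "f_i_po", "f_i_iv", "frac_m1_po", "frac_m1_iv"):
            assert sfm1[key] == pytest.approx(tm[key], abs=1e-9)

    def test_volume_invariance_of_auc_fractions(self, worked):
        drug, phys, spec = worked
        fs1 = sf.fsys_from_sim(sf.build_model(drug, phys, spec))
        scaled = phys.model_copy(
            update={k: getattr(phys, k) * 7.0
                    for k in ("v_b", "v_lumen", "v_eb", "v_ec", "v_ser",
                              "v_lb", "v_lc")}
        )
        fs2 = sf.fsys_from_sim(sf.build_model(drug, scaled, spec))
        for key in ("f_sys", "frac_m1_po", "frac_m2_po", "frac_m1_iv",
                    "frac_m2_iv", "f_i_po", "f_i_iv"):
            assert fs2[key] == pytest.approx(fs1[key], rel=1e-9)


class TestRouteDependence:
    def test_availability_ordering_chain(self, fixtures):
        """F_I,po,SFM < F_I,po,TM = F_I,iv,TM < F_I,iv,SFM for a drug whose
        transport does not limit tissue access."""
        nl = fixtures["permeability_nonlimited_victim"]
        tm = fixtures["permeability_nonlimited_victim_tm"]
        a = sf.fsys_from_sim(sf.build_model(nl.drug, nl.physiology, nl.spec))
        b = sf.fsys_from_sim(sf.build_model(tm.drug, tm.physiology, tm.spec))
        assert a["f_i_po"] < b["f_i_po"]
        assert abs(b["f_i_po"] - b["f_i_iv"]) < 1e-6
        assert b["f_i_iv"] < a["f_i_iv"]

    def test_sfm_po_maximizes_and_sfm_iv_minimizes_m1(self, fixtures):
        hp = fixtures["highly_permeable_victim"]
        tm = fixtures["highly_permeable_victim_tm"]
        a = sf.fsys_from_sim(sf.build_model(hp.drug, hp.physiology, hp.spec))
        b = sf.fsys_from_sim(sf.build_model(tm.drug, tm.physiology, tm.spec))
        m1 = {
            ("SFM", "po"): a["frac_m1_po"], ("SFM", "iv"): a["frac_m1_iv"],
            ("TM", "po"): b["frac_m1_po"], ("TM", "iv"): b["frac_m1_iv"],
        }
        assert max(m1, key=m1.get) == ("SFM", "po")
        assert min(m1, key=m1.get) == ("SFM", "iv")

    def test_metabolite_ratio_smaller_for_iv_when_qha_positive(self, fixtures):
        hp = fixtures["highly_permeable_victim"]
        model = sf.build_model(hp.drug, hp.physiology, hp.spec)
        grid = _grid(24.0, 49)
        sim_po = sf.simulate(model, [sf.DoseEvent(route="po", amount=1.0)], grid)
        sim_iv = sf.simulate(model, [sf.DoseEvent(route="iv", amount=1.0)], grid)
        res = sf.metabolite_ratio(sim_po, sim_iv)
        assert res["ratio_iv"] < res["ratio_po"]
        assert res["ordering"] == "iv < po"

    def test_no_hepatic_arterial_flow_makes_tm_route_blind(self, fixtures):
        """Without Q_HA the TM forms identical M1 and M2 either route."""
        nl = fixtures["permeability_nonlimited_victim_tm"]
        phys0 = nl.physiology.model_copy(update={"q_ha": 0.0})
        fs = sf.fsys_from_sim(sf.build_model(nl.drug, phys0, nl.spec))
        assert abs(fs["frac_m1_po"] - fs["frac_m1_iv"]) < 1e-6
        assert abs(fs["frac_m2_po"] - fs["frac_m2_iv"]) < 1e-6

    def test_ratio_undefined_without_hepatic_metabolism(self, fixtures):
        hp = fixtures["highly_permeable_victim"]
        drug = hp.drug.model_copy(update={"cl_int_met_h": 0.0})
        model = sf.build_model(drug, hp.physiology, hp.spec)
        grid = _grid(24.0, 25)
        sim_po = sf.simulate(model, [sf.DoseEvent(route="po", amount=1.0)], grid)
        sim_iv = sf.simulate(model, [sf.DoseEvent(route="iv", amount=1.0)], grid)
        with pytest.warns(RuntimeWarning, match="ratio undefined"):
            res = sf.metabolite_ratio(sim_po, sim_iv)
        assert res["ordering"] == "undefined"


class TestSSFM:
    def test_single_segment_reproduces_build_model_exactly(self, worked):
        drug, phys, spec = worked
        single = sf.build_model(drug, phys, spec)
        ssfm1 = sf.build_ssfm([{}], drug, phys, spec)
        assert np.array_equal(single.A, ssfm1.A)
        assert np.array_equal(single.volumes, ssfm1.volumes)

    def test_no_clearances_availability_is_net_absorption(self, fixtures):
        spec = sf.FlowModelSpec(variant="SSFM", f_q=0.1, n_segments=3)
        drug = sf.DrugParams(f_a=0.8, k_a=3.0, cl_d1_i=5, cl_d2_i=5,
                             cl_d1_h=5, cl_d2_h=5)
        model = sf.build_ssfm([{}, {}, {}], drug, fixtures["physiology"], spec)
        ra = sf.route_availability(model)
        k_t = 3.0 * (1 - 0.8) / 0.8
        expected = 1.0 - (k_t / (3.0 + k_t)) ** 3
        f_sys = ra["f_a_realized"] * ra["f_i_po"] * ra["f_h_first_pass"]
        assert f_sys == pytest.approx(expected, rel=1e-9)

    def test_proximal_metabolism_distal_secretion_lowers_availability(
        self, fixtures
    ):
        """The physiological CYP3A-proximal / P-gp-distal pattern removes more
        drug than a uniform distribution of the same totals."""
        spec = sf.FlowModelSpec(variant="SSFM", f_q=0.1, n_segments=3)
        hp = fixtures["highly_permeable_victim"]
        drug = hp.drug.model_copy(update={"f_a": 0.85, "cl_int_sec_i": 0.9,
                                          "cl_int_met1_i": 0.9})
        uniform = [{"cl_int_met1_i": 0.3, "cl_int_sec_i": 0.3}] * 3
        hetero = [
            {"cl_int_met1_i": 0.6, "cl_int_sec_i": 0.05},
            {"cl_int_met1_i": 0.2, "cl_int_sec_i": 0.25},
            {"cl_int_met1_i": 0.1, "cl_int_sec_i": 0.6},
        ]
        phys = fixtures["physiology"]
        f_u = sf.fsys_from_sim(sf.build_ssfm(uniform, drug, phys, spec))["f_sys"]
        f_h = sf.fsys_from_sim(sf.build_ssfm(hetero, drug, phys, spec))["f_sys"]
        assert f_h < f_u

    def test_mismatched_segment_list_rejected(self, worked):
        drug, phys, _ = worked
        spec = sf.FlowModelSpec(variant="SSFM", f_q=0.1, n_segments=3)
        with pytest.raises(ValueError, match="n_segments"):
            sf.build_ssfm([{}, {}], drug, phys, spec)
        with pytest.raises(ValueError, match="unknown segment"):
            sf.build_ssfm([{"bogus": 1.0}] * 3, drug, phys, spec)

    def test_ssfm_mass_balance(self, fixtures):
        spec = sf.FlowModelSpec(variant="SSFM", f_q=0.1, n_segments=3)
        hp = fixtures["highly_permeable_victim"]
        model = sf.build_ssfm([{}] * 3, hp.drug, hp.physiology, spec)
        sim = sf.simulate(model, [sf.DoseEvent(route="po", amount=1.0)],
                          _grid(24.0, 25))
        assert sim.mass_balance_error() < 1e-8
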