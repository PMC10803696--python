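"""Parameter-table loading, virtual patients and whole-body model structure."""

import math
import warnings

import numpy as np
import pytest

from pbrpk import (
    InjectionSchedule,
    ModelOptions,
    SolverSettings,
    ValidationError,
    build_pbrpk_model,
    enumerate_patient_grid,
    load_parameter_table,
    make_virtual_patient,
    simulate,
)
from pbrpk.graph import ALBUMIN_KINDS, HOT_KINDS, LIGAND_KINDS, RECEPTOR_KINDS
from tests.conftest import patient_model


class TestParameterTable:
    def test_default_table_loads_with_enough_organs(self, base_params):
        assert len(base_params.organs) >= 18
        assert base_params.lambda_phys == pytest.approx(
            math.log(2) / (6.647 * 1440), rel=1e-3
        )
        assert math.isinf(base_params.K_D_alb)

    def test_missing_key_is_named(self):
        import yaml
        from importlib import resources

        doc = yaml.safe_load(
            resources.files("pbrpk").joinpath("data", "psma_lu177_params.yaml").read_text()
        )
        del doc["global"]["gfr_L_per_min"]
        with pytest.raises(ValidationError, match="gfr_L_per_min"):
            load_parameter_table(doc)

    def test_per_ml_receptor_density_converted(self):
        import yaml
        from importlib import resources

        doc = yaml.safe_load(
            resources.files("pbrpk").joinpath("data", "psma_lu177_params.yaml").read_text()
        )
        entry = dict(doc["organs"][0])
        entry["receptor_density_nmol_per_mL"] = 0.015
        del entry["receptor_density_nmol_per_L"]
        doc["organs"][0] = entry
        base = load_parameter_table(doc)
        assert base.organs[0].receptor_density == pytest.approx(15.0)

    def test_k_off_is_derived(self, base_params):
        assert base_params.k_off == base_params.k_on * base_params.K_D


class TestVirtualPatients:
    @pytest.mark.parametrize("vol,dens", [(40.0, 10.0), (2100.0, 890.0)])
    def test_sweep_bounds_are_valid_patients(self, base_params, vol, dens):
        p = make_virtual_patient(base_params, vol, dens)
        assert p.tumor.volume == pytest.approx(vol / 1000.0)
        assert p.tumor.receptor_amount == pytest.approx(dens * vol / 1000.0)

    def test_nonpositive_inputs_rejected(self, base_params):
        with pytest.raises(ValidationError):
            make_virtual_patient(base_params, 0.0, 10.0)

    def test_out_of_range_warns(self, base_params):
        with pytest.warns(UserWarning):
            make_virtual_patient(base_params, 20.0, 40.0)

    def test_patient_grid_is_volume_major_cartesian_product(self, base_params):
        vols = list(np.linspace(40.0, 2100.0, 10))
        dens = list(np.linspace(10.0, 890.0, 10))
        grid = enumerate_patient_grid(vols, dens, base_params)
        assert len(grid) == 100
        assert grid[0].tumor_volume_ml == pytest.approx(40.0)
        assert grid[-1].tumor_volume_ml == pytest.approx(2100.0)
        assert grid[1].tumor_volume_ml == pytest.approx(40.0)  # volume-major
        single = enumerate_patient_grid([100.0], [50.0], base_params)
        assert single[0] == make_virtual_patient(base_params, 100.0, 50.0)

    def test_empty_grid_rejected(self, base_params):
        with pytest.raises(ValidationError):
            enumerate_patient_grid([], [10.0], base_params)


class TestModelStructure:
    def test_albumin_disabled_has_no_albumin_species(self, preset_model):
        assert not preset_model.species_by_kind(*ALBUMIN_KINDS)

    def test_full_model_exceeds_150_states(self, base_params):
        g = patient_model(base_params, 100.0, 40.0, albumin_kd=50.0)
        assert len(g.species) > 150

    def test_albumin_complexes_are_never_cleared(self, base_params):
        g = patient_model(base_params, 100.0, 40.0, albumin_kd=50.0)
        for r in g.reactions:
            if r.tag != "clearance":
                continue
            kinds = {g.species[sid].kind for sid, _ in r.reactants}
            assert kinds <= {"hot_ligand", "cold_ligand"}

    def test_albumin_confined_to_plasma_except_tumor(self, base_params):
        g = patient_model(base_params, 100.0, 40.0, albumin_kd=50.0)
        for s in g.species_by_kind(*ALBUMIN_KINDS):
            comp = g.compartments[s.compartment]
            assert comp.subspace in ("vascular", "blood_pool") or comp.organ == "tumor"

    def test_graph_validates(self, base_params):
        assert patient_model(base_params, 100.0, 40.0, albumin_kd=50.0).validate() == []


class TestConservationOnTrajectories:
    def test_ligand_albumin_receptor_conservation(self, base_params, fast_settings):
        g = patient_model(base_params, 100.0, 40.0, albumin_kd=50.0)
        sched = InjectionSchedule(10.0, 100.0, n_injections=3, interval=200.0)
        res = simulate(g, sched, fast_settings)
        lig = res.total_amount(LIGAND_KINDS)
        # after the last bolus the ligand moiety count is the injected total
        after = res.times >= sched.bolus_times[-1]
        assert np.max(np.abs(lig[after] - 110.0)) / 110.0 < 1e-6
        alb = res.total_amount(ALBUMIN_KINDS)
        assert np.ptp(alb) / alb[0] < 1e-6
        for organ in ("tumor", "kidneys", "salivary_glands"):
            rec = res.organ_amount(organ, RECEPTOR_KINDS)
            assert np.ptp(rec) / rec[0] < 1e-6

    def test_hot_decays_at_physical_rate_after_last_bolus(self, base_params, fast_settings):
        g = patient_model(base_params, 100.0, 40.0)
        sched = InjectionSchedule(10.0, 100.0, n_injections=2, interval=300.0)
        res = simulate(g, sched, fast_settings)
        hot = res.total_amount(HOT_KINDS)
        lam = base_params.lambda_phys
        after = res.times >= 300.0
        t = res.times[after]
        pred = hot[after][0] * np.exp(-lam * (t - t[0]))
        assert np.max(np.abs(hot[after] - pred) / pred) < 1e-6

    def test_kd_alb_infinity_matches_disabled_model(self, base_params, fast_settings):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            p_inf = make_virtual_patient(base_params.with_K_D_alb(math.inf), 100.0, 40.0)
            p_off = make_virtual_patient(base_params, 100.0, 40.0)
        g_inf = build_pbrpk_model(p_inf, ModelOptions(albumin_enabled=True))
        g_off = build_pbrpk_model(p_off, ModelOptions(albumin_enabled=False))
        sched = InjectionSchedule(10.0, 100.0)
        r_inf = simulate(g_inf, sched, fast_settings)
        r_off = simulate(g_off, sched, fast_settings)
        assert r_inf.species_ids == r_off.species_ids
        denom = np.abs(r_off.amounts) + 1e-30
        assert np.max(np.abs(r_inf.amounts - r_off.amounts) / denom) < 1e-9
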