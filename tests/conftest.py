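"""Shared fixtures: parameter table, patient models and precomputed sweeps.

Expensive whole-body sweeps are session-scoped so the qualitative trend
tests and the metric tests share one set of simulations.
"""

import warnings

import numpy as np
import pytest

from pbrpk import (
    DoseGrid,
    InjectionSchedule,
    ModelOptions,
    SolverSettings,
    build_pbrpk_model,
    dose_report,
    load_parameter_table,
    make_virtual_patient,
    simulate,
)

ORGANS = ("tumor", "kidneys", "salivary_glands")

# reduced sweep axes used by the trend tests (endpoints match the study grids)
HOTS = np.linspace(5.0, 100.0, 5)
COLDS = np.linspace(25.0, 800.0, 5)


@pytest.fixture(scope="session")
def base_params():
    return load_parameter_table()


@pytest.fixture(scope="session")
def preset_model(base_params):
    """Figure-preset patient: 20 mL tumor, 40 nmol/L receptors, no albumin."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        patient = make_virtual_patient(base_params, 20.0, 40.0)
    return build_pbrpk_model(patient, ModelOptions(albumin_enabled=False))


def patient_model(base, volume_ml, density, albumin_kd=None):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        b = base if albumin_kd is None else base.with_K_D_alb(albumin_kd)
        patient = make_virtual_patient(b, volume_ml, density)
    return build_pbrpk_model(
        patient, ModelOptions(albumin_enabled=albumin_kd is not None)
    )


def organ_doses(result, base, organs=ORGANS):
    rep = dose_report(
        result, delta=base.mean_energy_per_decay, density=base.tissue_density, organs=list(organs)
    )
    return {o: rep.dose(o) for o in organs}


def sweep_dose_grids(base, volume_ml, density):
    """5x5 hot/cold single-bolus sweep; one DoseGrid per reported organ."""
    graph = patient_model(base, volume_ml, density)
    doses = np.zeros((len(HOTS), len(COLDS), len(ORGANS)))
    for i, h in enumerate(HOTS):
        for j, c in enumerate(COLDS):
            res = simulate(graph, InjectionSchedule(float(h), float(c)))
            d = organ_doses(res, base)
            for k, o in enumerate(ORGANS):
                doses[i, j, k] = d[o]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return {
            o: DoseGrid(HOTS, COLDS, doses[:, :, k], o) for k, o in enumerate(ORGANS)
        }


@pytest.fixture(scope="session")
def hotcold_grids(base_params):
    """Dose grids for the four patient settings the trend tests compare:

    (volume mL, receptor density nmol/L) in {(20,40), (20,400), (40,40), (2100,40)}.
    """
    settings = {
        (20.0, 40.0),
        (20.0, 400.0),
        (40.0, 40.0),
        (2100.0, 40.0),
    }
    return {vd: sweep_dose_grids(base_params, *vd) for vd in sorted(settings)}


@pytest.fixture(scope="session")
def albumin_sweep(base_params):
    """Doses and BRT over a reduced K_D^alb grid plus the disabled baseline."""
    import math

    from pbrpk import blood_residence_time

    kds = list(np.logspace(np.log10(5.0), 5.0, 10))
    out = {}
    for kd in [math.inf, *kds]:
        graph = patient_model(
            base_params, 20.0, 40.0, albumin_kd=None if math.isinf(kd) else kd
        )
        res = simulate(graph, InjectionSchedule(10.0, 100.0))
        out[kd] = {
            **organ_doses(res, base_params),
            "brt": blood_residence_time(res),
        }
    return out


@pytest.fixture(scope="session")
def fractionation_tables(base_params):
    """Tumor-dose tables over (n, tau) for a low and a high receptor density."""
    tables = {}
    for dens in (43.0, 342.0):
        graph = patient_model(base_params, 20.0, dens)
        res0 = simulate(graph, InjectionSchedule(10.0, 100.0))
        baseline = organ_doses(res0, base_params)["tumor"]
        tab = {}
        for n in (2, 5, 10):
            for tau in (100.0, 500.0, 1000.0):
                res = simulate(graph, InjectionSchedule(10.0, 100.0, n, tau))
                tab[(n, tau)] = organ_doses(res, base_params)["tumor"]
        tables[dens] = {"baseline": baseline, "table": tab}
    return tables


@pytest.fixture(scope="session")
def fast_settings():
    return SolverSettings(t_end=2000.0, n_grid=80)
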