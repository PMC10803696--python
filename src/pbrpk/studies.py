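"""End-to-end virtual-patient studies.

Three reproducible pipelines over deterministic parameter grids:

* ``hotcold`` — single-bolus sweeps over injected hot × cold amounts and
  virtual patients; produces per-organ dose grids and twist profiles.
* ``injection`` — multi-bolus sweeps over (number of injections n, spacing
  τ) at fixed totals (10 nmol hot / 100 nmol cold, equal split); produces
  MRDC per patient and organ.
* ``albumin`` — sweep over the albumin dissociation constant K_D^alb plus
  the albumin-disabled baseline; produces BRT and enhancement-factor
  curves against each OAR.

Everything is deterministic: identical specs give bit-identical tables.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .dosimetry import blood_residence_time, dose_report
from .errors import ValidationError
from .metrics import DoseGrid, EFCurve, MRDCResult, TwistProfile, compute_ef, compute_mrdc, compute_twist
from .physiology import (
    GlobalParameters,
    ModelOptions,
    build_pbrpk_model,
    load_parameter_table,
    make_virtual_patient,
)
from .simulation import InjectionSchedule, SolverSettings, simulate

STUDY_KINDS = ("hotcold", "injection", "albumin")

DEFAULT_ORGANS = ("tumor", "kidneys", "salivary_glands")

#: figure-preset tumor parameters (volume in mL, receptor density in nmol/L)
PRESET_TUMOR_VOLUME_ML = 20.0
PRESET_RECEPTOR_DENSITY = 40.0


@dataclass(frozen=True)
class StudySpec:
    kind: str
    base: GlobalParameters
    grids: dict = field(default_factory=dict)
    organs: tuple[str, ...] = DEFAULT_ORGANS
    settings: SolverSettings = field(default_factory=SolverSettings)
    hot_total: float = 10.0  # nmol (injection/albumin studies)
    cold_total: float = 100.0  # nmol
    injection_coefficient: int = 1  # inert label; no semantics attached

    def __post_init__(self):
        if self.kind not in STUDY_KINDS:
            raise ValidationError(f"unknown study kind {self.kind!r}")


@dataclass
class StudyResult:
    spec: StudySpec
    table: pd.DataFrame  # long form, one row per (grid point, organ)
    dose_grids: dict = field(default_factory=dict)  # hotcold: (vol, dens, organ) -> DoseGrid
    twist: dict = field(default_factory=dict)  # hotcold: (vol, dens, organ) -> TwistProfile
    mrdc: dict = field(default_factory=dict)  # injection: (vol, dens, organ) -> MRDCResult
    brt: dict = field(default_factory=dict)  # albumin: kd -> minutes (inf key = baseline)
    ef: dict = field(default_factory=dict)  # albumin: oar -> EFCurve


def default_spec(kind: str, base: GlobalParameters | None = None, **overrides) -> StudySpec:
    """Study presets with the published sweep grids."""
    base = base or load_parameter_table()
    if kind == "hotcold":
        grids = {
            "hot": list(np.linspace(5.0, 100.0, 10)),
            "cold": list(np.linspace(25.0, 800.0, 10)),
            "receptor_density": list(np.linspace(10.0, 890.0, 10)),
            "tumor_volume_ml": list(np.linspace(40.0, 2100.0, 10)),
        }
    elif kind == "injection":
        grids = {
            "n_injections": list(range(1, 11)),
            "interval": [10.0, 50.0, 100.0, 200.0, 300.0, 400.0, 500.0, 750.0, 1000.0],
            "receptor_density": list(np.linspace(43.0, 342.0, 10)),
            "tumor_volume_ml": list(np.linspace(40.0, 2100.0, 10)),
        }
    elif kind == "albumin":
        grids = {
            "kd_alb": list(np.logspace(np.log10(5.0), 5.0, 20)),
            "receptor_density": [PRESET_RECEPTOR_DENSITY],
            "tumor_volume_ml": [PRESET_TUMOR_VOLUME_ML],
        }
    else:
        raise ValidationError(f"unknown study kind {kind!r}")
    grids.update(overrides.pop("grids", {}))
    return StudySpec(kind=kind, base=base, grids=grids, **overrides)


def scale_grid(spec: StudySpec, factor: int) -> StudySpec:
    """Subsample every grid axis to ceil(size/factor) points, keeping endpoints."""
    if factor < 1:
        raise ValidationError("scale factor must be >= 1")
    if factor == 1:
        return spec
    grids = {}
    for name, values in spec.grids.items():
        values = list(values)
        n_keep = math.ceil(len(values) / factor)
        idx = np.unique(np.round(np.linspace(0, len(values) - 1, n_keep)).astype(int))
        grids[name] = [values[i] for i in idx]
    return replace(spec, grids=grids)


def _organ_doses(result, base: GlobalParameters, organs) -> dict[str, float]:
    rep = dose_report(
        result, delta=base.mean_energy_per_decay, density=base.tissue_density, organs=list(organs)
    )
    return {o: rep.dose(o) for o in organs}


def run_hotcold_study(spec: StudySpec) -> StudyResult:
    if spec.kind != "hotcold":
        raise ValidationError("spec kind must be 'hotcold'")
    hots = np.asarray(spec.grids["hot"], dtype=float)
    colds = np.asarray(spec.grids["cold"], dtype=float)
    rows = []
    dose_grids: dict = {}
    twists: dict = {}
    for vol in spec.grids["tumor_volume_ml"]:
        for dens in spec.grids["receptor_density"]:
            patient = make_virtual_patient(spec.base, vol, dens)
            graph = build_pbrpk_model(patient, ModelOptions(albumin_enabled=False))
            doses = np.zeros((len(hots), len(colds), len(spec.organs)))
            for i, hot in enumerate(hots):
                for j, cold in enumerate(colds):
                    sched = InjectionSchedule(hot_total=float(hot), cold_total=float(cold))
                    res = simulate(graph, sched, spec.settings)
                    d = _organ_doses(res, spec.base, spec.organs)
                    for k, organ in enumerate(spec.organs):
                        doses[i, j, k] = d[organ]
                        rows.append(
                            {
                                "tumor_volume_ml": vol,
                                "receptor_density": dens,
                                "hot_nmol": float(hot),
                                "cold_nmol": float(cold),
                                "organ": organ,
                                "dose_gy": d[organ],
                            }
                        )
            for k, organ in enumerate(spec.organs):
                grid = DoseGrid(hot=hots, cold=colds, dose=doses[:, :, k], organ=organ)
                dose_grids[(vol, dens, organ)] = grid
                if len(hots) >= 3 and len(colds) >= 3:
                    try:
                        twists[(vol, dens, organ)] = compute_twist(grid)
                    except ValidationError:
                        pass
    return StudyResult(
        spec=spec, table=pd.DataFrame(rows), dose_grids=dose_grids, twist=twists
    )


def run_injection_study(spec: StudySpec) -> StudyResult:
    if spec.kind != "injection":
        raise ValidationError("spec kind must be 'injection'")
    rows = []
    mrdc: dict = {}
    for vol in spec.grids["tumor_volume_ml"]:
        for dens in spec.grids["receptor_density"]:
            patient = make_virtual_patient(spec.base, vol, dens)
            graph = build_pbrpk_model(patient, ModelOptions(albumin_enabled=False))
            base_res = simulate(
                graph,
                InjectionSchedule(hot_total=spec.hot_total, cold_total=spec.cold_total),
                spec.settings,
            )
            baseline = _organ_doses(base_res, spec.base, spec.organs)
            tables: dict[str, dict] = {o: {} for o in spec.organs}
            for n in spec.grids["n_injections"]:
                for tau in spec.grids["interval"]:
                    if n == 1 and tau != spec.grids["interval"][0]:
                        continue  # a single bolus is tau-independent
                    sched = InjectionSchedule(
                        hot_total=spec.hot_total,
                        cold_total=spec.cold_total,
                        n_injections=int(n),
                        interval=float(tau) if n > 1 else 0.0,
                    )
                    res = simulate(graph, sched, spec.settings)
                    d = _organ_doses(res, spec.base, spec.organs)
                    for organ in spec.organs:
                        key = (int(n), float(tau) if n > 1 else 0.0)
                        tables[organ][key] = d[organ]
                        rows.append(
                            {
                                "tumor_volume_ml": vol,
                                "receptor_density": dens,
                                "n_injections": int(n),
                                "interval_min": key[1],
                                "organ": organ,
                                "dose_gy": d[organ],
                            }
                        )
            for organ in spec.organs:
                mrdc[(vol, dens, organ)] = compute_mrdc(
                    tables[organ], baseline[organ], organ=organ
                )
    return StudyResult(spec=spec, table=pd.DataFrame(rows), mrdc=mrdc)


def run_albumin_study(spec: StudySpec) -> StudyResult:
    if spec.kind != "albumin":
        raise ValidationError("spec kind must be 'albumin'")
    kds = sorted(float(k) for k in spec.grids["kd_alb"])
    vol = spec.grids["tumor_volume_ml"][0]
    dens = spec.grids["receptor_density"][0]
    sched = InjectionSchedule(hot_total=spec.hot_total, cold_total=spec.cold_total)

    rows = []
    brt: dict = {}
    doses_by_kd: dict[float, dict[str, float]] = {}
    for kd in [math.inf, *kds]:
        base = spec.base.with_K_D_alb(kd)
        patient = make_virtual_patient(base, vol, dens)
        graph = build_pbrpk_model(
            patient, ModelOptions(albumin_enabled=not math.isinf(kd))
        )
        res = simulate(graph, sched, spec.settings)
        d = _organ_doses(res, spec.base, spec.organs)
        doses_by_kd[kd] = d
        brt[kd] = blood_residence_time(res)
        for organ in spec.organs:
            rows.append(
                {
                    "tumor_volume_ml": vol,
                    "receptor_density": dens,
                    "kd_alb": kd,
                    "organ": organ,
                    "dose_gy": d[organ],
                    "brt_min": brt[kd],
                }
            )

    ef: dict[str, EFCurve] = {}
    for oar in spec.organs:
        if oar == "tumor":
            continue
        ef[oar] = compute_ef(
            {kd: doses_by_kd[kd]["tumor"] for kd in kds},
            {kd: doses_by_kd[kd][oar] for kd in kds},
            tumor_base=doses_by_kd[math.inf]["tumor"],
            oar_base=doses_by_kd[math.inf][oar],
            oar=oar,
        )
    return StudyResult(spec=spec, table=pd.DataFrame(rows), brt=brt, ef=ef)


def run_study(spec: StudySpec) -> StudyResult:
    return {
        "hotcold": run_hotcold_study,
        "injection": run_injection_study,
        "albumin": run_albumin_study,
    }[spec.kind](spec)
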