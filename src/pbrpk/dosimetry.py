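"""Dosimetry: activities, time-integrated activities, absorbed dose, BRT.

Activity of an organ is λ_phys × (total hot-moiety amount in the organ),
converted to becquerel: every hot form contributes — free, receptor-bound,
internalized and albumin-complexed ligand all carry the radiolabel.
Absorbed dose uses the local-deposition (self-dose) model appropriate for a
β⁻ emitter: dose = (number of decays) × Δ / organ mass, so dose and TIA
differ only by a fixed per-organ constant.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ValidationError
from .graph import HOT_KINDS, ReactionGraph
from .simulation import SimulationResult

AVOGADRO = 6.02214076e23
#: Bq per (nmol × per-minute decay constant): λ[1/min]/60 × nmol×1e-9×N_A
BQ_PER_NMOL_LAMBDA_MIN = 1e-9 * AVOGADRO / 60.0


@dataclass(frozen=True)
class TimeActivityCurve:
    organ: str
    times: np.ndarray  # min
    activity: np.ndarray  # Bq

    def __post_init__(self):
        if len(self.times) != len(self.activity):
            raise ValidationError("times and activity must have equal length")
        if np.any(self.activity < 0):
            raise ValidationError("activity must be >= 0")


def activity_tac(result: SimulationResult, organ: str) -> TimeActivityCurve:
    """λ_phys × summed hot-moiety amount in all compartments of *organ*, in Bq."""
    lam = result.graph.parameters.get("lambda_phys")
    if lam is None:
        raise ValidationError("graph has no 'lambda_phys' parameter")
    hot = result.organ_amount(organ, HOT_KINDS)
    return TimeActivityCurve(
        organ=organ,
        times=result.times,
        activity=lam * hot * BQ_PER_NMOL_LAMBDA_MIN,
    )


def time_integrated_activity(
    tac: TimeActivityCurve,
    t_end: float | None = None,
    lambda_phys: float | None = None,
    tail: bool = True,
) -> float:
    """∫₀^t_end A(τ)dτ in Bq·min, trapezoid on the TAC grid.

    With ``tail=True`` (default) an analytic exponential tail
    A(t_end)/λ_phys is added, assuming pure physical decay of the terminal
    activity — at a 50,000-minute horizon (≈5.2 ¹⁷⁷Lu half-lives) the tail
    is small but not negligible.
    """
    times, act = tac.times, tac.activity
    if t_end is not None:
        if t_end > times[-1] + 1e-9:
            raise ValidationError("t_end beyond the available TAC data")
        mask = times <= t_end
        times, act = times[mask], act[mask]
        if times[-1] < t_end:  # close the interval exactly
            a_end = np.interp(t_end, tac.times, tac.activity)
            times = np.append(times, t_end)
            act = np.append(act, a_end)
    tia = float(np.trapezoid(act, times))
    if tail:
        if lambda_phys is None:
            raise ValidationError("tail extrapolation requires lambda_phys")
        if lambda_phys > 0:
            tia += float(act[-1]) / lambda_phys
    return tia


def absorbed_dose(tia: float, organ_mass: float, delta: float) -> float:
    """Self-dose in Gy: (decays = TIA[Bq·min]×60) × Δ[J] / mass[kg]."""
    if organ_mass <= 0:
        raise ValidationError("organ mass must be > 0")
    if tia < 0:
        raise ValidationError("TIA must be >= 0")
    return tia * 60.0 * delta / organ_mass


def blood_residence_time(result: SimulationResult, t_end: float | None = None) -> float:
    """Vein-compartment TIA over injected activity, in minutes.

    BRT = ∫ A_vein dτ / A₀ with A₀ = λ_phys·H₀; the λ's and the activity
    unit cancel, so this is ∫ H_vein dt / H₀ directly.
    """
    if result.schedule is None or result.schedule.hot_total <= 0:
        raise ValidationError("BRT requires a schedule with injected hot > 0")
    lam = result.graph.parameters.get("lambda_phys", 0.0)
    tac = activity_tac(result, "vein")
    if not np.any(tac.activity > 0):
        return 0.0
    tia = time_integrated_activity(tac, t_end=t_end, lambda_phys=lam, tail=t_end is None)
    a0 = lam * result.schedule.hot_total * BQ_PER_NMOL_LAMBDA_MIN
    if a0 <= 0:
        raise ValidationError("injected activity is zero")
    return tia / a0


@dataclass
class DoseReport:
    """Per-organ TIA, mass and absorbed dose, plus the constants used."""

    table: pd.DataFrame  # columns: organ, tia_bq_min, mass_kg, dose_gy
    delta: float  # J per decay
    density: float  # kg/L

    def dose(self, organ: str) -> float:
        row = self.table.loc[self.table["organ"] == organ]
        if row.empty:
            raise ValidationError(f"no organ {organ!r} in dose report")
        return float(row["dose_gy"].iloc[0])

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def organ_masses(graph: ReactionGraph, density: float) -> dict[str, float]:
    """Organ mass = physical compartment volume × soft-tissue density.

    Membrane compartments are bookkeeping containers for the receptor pool
    (their volume mirrors the interstitial space for concentration
    conversion) and carry no additional physical volume.
    """
    vols: dict[str, float] = {}
    for c in graph.compartments.values():
        if c.subspace == "membrane":
            continue
        vols[c.organ] = vols.get(c.organ, 0.0) + c.volume
    return {o: v * density for o, v in vols.items()}


def dose_report(
    result: SimulationResult,
    delta: float,
    density: float = 1.04,
    organs=None,
    t_end: float | None = None,
) -> DoseReport:
    """Compute TIA and self-dose for every (or the given) organs."""
    graph = result.graph
    lam = graph.parameters.get("lambda_phys", 0.0)
    masses = organ_masses(graph, density)
    if organs is None:
        organs = [o for o in graph.organs() if o not in ("urine",)]
    rows = []
    for organ in organs:
        tac = activity_tac(result, organ)
        tia = time_integrated_activity(tac, t_end=t_end, lambda_phys=lam, tail=True)
        rows.append(
            {
                "organ": organ,
                "tia_bq_min": tia,
                "mass_kg": masses[organ],
                "dose_gy": absorbed_dose(tia, masses[organ], delta),
            }
        )
    return DoseReport(table=pd.DataFrame(rows), delta=delta, density=density)
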