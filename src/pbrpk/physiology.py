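"""Whole-body PBRPK model construction.

Builds the full ¹⁷⁷Lu-PSMA-like reaction graph from a physiological
parameter table and a *virtual patient* (a tumor volume / tumor receptor
density override on the shared population physiology).

Model structure, per organ:

* a vascular compartment fed from the arterial pool and draining to the
  venous pool at the organ's plasma flow;
* permeability exchange (PS product) between vascular and interstitial
  space for free hot/cold ligand;
* for receptor-expressing organs, a finite membrane receptor pool with
  reversible binding of free interstitial ligand (k_on, k_off = k_on·K_D),
  internalization of the bound complex (receptor recycled to the free
  pool, ligand moved to the intracellular space) and slow intracellular
  release back to the interstitium;
* renal filtration of free vascular ligand from the kidney at GFR into an
  excreta (urine) compartment;
* physical decay hot→cold *in place* in every compartment and every bound
  form — the ligand molecule persists after its radionuclide decays and
  keeps competing for receptors.

The optional albumin extension adds an albumin binding-site pool to all
plasma compartments with reversible 1:1 ligand binding.  Complexes travel
with plasma flow, are never renally filtered, never bind receptors, and
leak across the vascular wall only in the tumor (porous tumor vasculature),
with the same permeability as the free ligand.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace
from importlib import resources

import yaml

from .errors import ValidationError
from .graph import CompartmentDef, RateLaw, ReactionDef, ReactionGraph, SpeciesDef

DEFAULT_PARAMS_RESOURCE = "psma_lu177_params.yaml"

#: tumor sweep ranges used across the studies; wider values only warn
TUMOR_VOLUME_RANGE_ML = (40.0, 2100.0)
RECEPTOR_DENSITY_RANGE = (10.0, 890.0)


@dataclass(frozen=True)
class OrganParameters:
    """Population physiology of one organ (volumes in L, flows in L/min)."""

    name: str
    volume: float
    vascular_fraction: float
    interstitial_fraction: float
    plasma_flow: float
    receptor_density: float  # nmol per L organ; 0 for non-expressing organs
    permeability: float  # vascular<->interstitial PS product, L/min

    def __post_init__(self):
        if self.volume <= 0 or self.plasma_flow < 0 or self.permeability < 0:
            raise ValidationError(f"organ {self.name!r}: non-physical volume/flow/PS")
        if not (0 < self.vascular_fraction < 1 and 0 < self.interstitial_fraction < 1):
            raise ValidationError(f"organ {self.name!r}: fractions must be in (0,1)")
        if self.vascular_fraction + self.interstitial_fraction >= 1:
            raise ValidationError(f"organ {self.name!r}: fractions must sum < 1")
        if self.receptor_density < 0:
            raise ValidationError(f"organ {self.name!r}: negative receptor density")

    @property
    def vascular_volume(self) -> float:
        return self.volume * self.vascular_fraction

    @property
    def interstitial_volume(self) -> float:
        return self.volume * self.interstitial_fraction

    @property
    def cellular_volume(self) -> float:
        return self.volume * (1 - self.vascular_fraction - self.interstitial_fraction)

    @property
    def receptor_amount(self) -> float:
        """Total binding-site amount, nmol (density × total organ volume)."""
        return self.receptor_density * self.volume


@dataclass(frozen=True)
class TumorScaling:
    """How tumor flow and permeability scale with tumor volume."""

    perfusion_per_min: float  # plasma flow per L tumor
    permeability_per_min: float  # PS per L tumor
    vascular_fraction: float
    interstitial_fraction: float


@dataclass(frozen=True)
class GlobalParameters:
    """Shared kinetic constants plus the organ table.

    ``K_D_alb = inf`` encodes "albumin binding disabled"; k_off values are
    always derived (k_off = k_on·K_D), never stored.
    """

    lambda_phys: float  # 1/min
    k_on: float  # L/(nmol min)
    K_D: float  # nmol/L
    lambda_int: float  # 1/min
    lambda_rel: float  # 1/min
    gfr: float  # L/min
    albumin_conc: float  # nmol/L plasma
    k_on_alb: float  # L/(nmol min)
    K_D_alb: float  # nmol/L; inf disables albumin binding
    tissue_density: float  # kg/L
    mean_energy_per_decay: float  # J
    arterial_volume: float  # L
    venous_volume: float  # L
    organs: tuple[OrganParameters, ...]
    tumor_scaling: TumorScaling

    def __post_init__(self):
        for name in ("lambda_phys", "k_on", "lambda_int", "lambda_rel", "gfr", "k_on_alb"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        if not (self.K_D > 0):
            raise ValidationError("K_D must be > 0")
        if not (self.K_D_alb > 0):
            raise ValidationError("K_D_alb must be in (0, inf]")

    @property
    def k_off(self) -> float:
        return self.k_on * self.K_D

    @property
    def k_off_alb(self) -> float:
        if math.isinf(self.K_D_alb):
            raise ValidationError("k_off_alb undefined when albumin binding is disabled")
        return self.k_on_alb * self.K_D_alb

    def organ(self, name: str) -> OrganParameters:
        for o in self.organs:
            if o.name == name:
                return o
        raise ValidationError(f"no organ named {name!r} in the parameter table")

    def with_K_D_alb(self, value: float) -> "GlobalParameters":
        return replace(self, K_D_alb=float(value))


@dataclass(frozen=True)
class VirtualPatient:
    """One model instance: population physiology + tumor volume/receptor density."""

    base: GlobalParameters
    tumor_volume_ml: float
    tumor_receptor_density: float  # nmol/L

    def __post_init__(self):
        if self.tumor_volume_ml <= 0 or self.tumor_receptor_density <= 0:
            raise ValidationError("tumor volume and receptor density must be > 0")
        lo, hi = TUMOR_VOLUME_RANGE_ML
        if not (lo <= self.tumor_volume_ml <= hi):
            warnings.warn(
                f"tumor volume {self.tumor_volume_ml} mL outside the studied "
                f"range [{lo}, {hi}] mL",
                stacklevel=2,
            )
        lo, hi = RECEPTOR_DENSITY_RANGE
        if not (lo <= self.tumor_receptor_density <= hi):
            warnings.warn(
                f"tumor receptor density {self.tumor_receptor_density} nmol/L "
                f"outside the studied range [{lo}, {hi}] nmol/L",
                stacklevel=2,
            )

    @property
    def tumor(self) -> OrganParameters:
        ts = self.base.tumor_scaling
        v = self.tumor_volume_ml / 1000.0  # mL -> L
        return OrganParameters(
            name="tumor",
            volume=v,
            vascular_fraction=ts.vascular_fraction,
            interstitial_fraction=ts.interstitial_fraction,
            plasma_flow=ts.perfusion_per_min * v,
            receptor_density=self.tumor_receptor_density,
            permeability=ts.permeability_per_min * v,
        )


@dataclass(frozen=True)
class ModelOptions:
    albumin_enabled: bool = False
    tumor_present: bool = True
    albumin_leaks_into_tumor_interstitium: bool = True


# -- parameter table loading ----------------------------------------------

_REQUIRED_GLOBAL = (
    "lambda_phys_per_min",
    "k_on_L_per_nmol_min",
    "K_D_nmol_per_L",
    "lambda_int_per_min",
    "lambda_rel_per_min",
    "gfr_L_per_min",
    "albumin_conc_nmol_per_L",
    "k_on_alb_L_per_nmol_min",
    "K_D_alb_nmol_per_L",
    "tissue_density_kg_per_L",
    "mean_energy_per_decay_J",
)

_REQUIRED_ORGAN = (
    "name",
    "volume_L",
    "plasma_flow_L_per_min",
    "vascular_fraction",
    "interstitial_fraction",
    "receptor_density_nmol_per_L",
    "permeability_L_per_min",
)


def load_parameter_table(source=None) -> GlobalParameters:
    """Load and validate a physiology table.

    *source* may be None (packaged default), a path, a file object, or an
    already-parsed mapping.  Missing keys raise a :class:`ValidationError`
    naming the key.  Receptor densities given per mL (key suffix
    ``_nmol_per_mL``) are converted to nmol/L.
    """
    if source is None:
        text = (
            resources.files("pbrpk").joinpath("data", DEFAULT_PARAMS_RESOURCE).read_text()
        )
        doc = yaml.safe_load(text)
    elif isinstance(source, dict):
        doc = source
    elif hasattr(source, "read"):
        doc = yaml.safe_load(source.read())
    else:
        with open(source) as fh:
            doc = yaml.safe_load(fh)

    for section in ("global", "blood", "organs", "tumor"):
        if section not in doc:
            raise ValidationError(f"parameter table missing section {section!r}")
    gl = dict(doc["global"])
    # accept per-mL receptor densities on organs, converting x1000
    for key in _REQUIRED_GLOBAL:
        if key not in gl:
            raise ValidationError(f"parameter table missing key {key!r}")
        if gl[key] is None or (not math.isinf(float(gl[key])) and float(gl[key]) < 0):
            raise ValidationError(f"parameter {key!r} must be a non-negative number")

    organs = []
    for entry in doc["organs"]:
        entry = dict(entry)
        if "receptor_density_nmol_per_mL" in entry:
            entry["receptor_density_nmol_per_L"] = (
                float(entry.pop("receptor_density_nmol_per_mL")) * 1000.0
            )
        if "volume_mL" in entry:
            entry["volume_L"] = float(entry.pop("volume_mL")) / 1000.0
        for key in _REQUIRED_ORGAN:
            if key not in entry:
                raise ValidationError(
                    f"organ entry {entry.get('name', '?')!r} missing key {key!r}"
                )
        organs.append(
            OrganParameters(
                name=str(entry["name"]),
                volume=float(entry["volume_L"]),
                vascular_fraction=float(entry["vascular_fraction"]),
                interstitial_fraction=float(entry["interstitial_fraction"]),
                plasma_flow=float(entry["plasma_flow_L_per_min"]),
                receptor_density=float(entry["receptor_density_nmol_per_L"]),
                permeability=float(entry["permeability_L_per_min"]),
            )
        )

    tum = doc["tumor"]
    scaling = TumorScaling(
        perfusion_per_min=float(tum["perfusion_per_min"]),
        permeability_per_min=float(tum["permeability_per_min"]),
        vascular_fraction=float(tum["vascular_fraction"]),
        interstitial_fraction=float(tum["interstitial_fraction"]),
    )
    return GlobalParameters(
        lambda_phys=float(gl["lambda_phys_per_min"]),
        k_on=float(gl["k_on_L_per_nmol_min"]),
        K_D=float(gl["K_D_nmol_per_L"]),
        lambda_int=float(gl["lambda_int_per_min"]),
        lambda_rel=float(gl["lambda_rel_per_min"]),
        gfr=float(gl["gfr_L_per_min"]),
        albumin_conc=float(gl["albumin_conc_nmol_per_L"]),
        k_on_alb=float(gl["k_on_alb_L_per_nmol_min"]),
        K_D_alb=float(gl["K_D_alb_nmol_per_L"]),
        tissue_density=float(gl["tissue_density_kg_per_L"]),
        mean_energy_per_decay=float(gl["mean_energy_per_decay_J"]),
        arterial_volume=float(doc["blood"]["arterial_volume_L"]),
        venous_volume=float(doc["blood"]["venous_volume_L"]),
        organs=tuple(organs),
        tumor_scaling=scaling,
    )


def make_virtual_patient(
    base: GlobalParameters, tumor_volume_ml: float, receptor_density: float
) -> VirtualPatient:
    return VirtualPatient(base, float(tumor_volume_ml), float(receptor_density))


def enumerate_patient_grid(volumes_ml, densities, base: GlobalParameters):
    """Cartesian product of tumor volumes × receptor densities, volume-major."""
    volumes_ml, densities = list(volumes_ml), list(densities)
    if not volumes_ml or not densities:
        raise ValidationError("patient grid axes must be non-empty")
    return [
        make_virtual_patient(base, v, d) for v in volumes_ml for d in densities
    ]


# -- model construction ----------------------------------------------------


def build_pbrpk_model(
    patient: VirtualPatient, options: ModelOptions | None = None
) -> ReactionGraph:
    """Assemble the full whole-body reaction graph for one virtual patient."""
    options = options or ModelOptions()
    p = patient.base
    albumin_on = options.albumin_enabled and not math.isinf(p.K_D_alb)
    if options.albumin_enabled and math.isinf(p.K_D_alb):
        # the K_D^alb = inf sentinel omits albumin machinery entirely so the
        # disabled model is the exact baseline, not a huge-k_off approximation
        albumin_on = False

    organs = list(p.organs)
    if options.tumor_present:
        organs.append(patient.tumor)

    g = ReactionGraph("pbrpk")
    g.set_parameter("lambda_phys", p.lambda_phys)
    g.set_parameter("k_on", p.k_on)
    g.set_parameter("K_D", p.K_D)
    g.set_parameter("k_off", p.k_off)
    g.set_parameter("lambda_int", p.lambda_int)
    g.set_parameter("lambda_rel", p.lambda_rel)
    g.set_parameter("gfr", p.gfr)
    if albumin_on:
        g.set_parameter("k_on_alb", p.k_on_alb)
        g.set_parameter("K_D_alb", p.K_D_alb)
        g.set_parameter("k_off_alb", p.k_off_alb)

    mobile_free = ("hot_ligand", "cold_ligand")
    alb_kinds = ("albumin", "hot_albumin_complex", "cold_albumin_complex")
    vascular_kinds = mobile_free + (alb_kinds if albumin_on else ())

    def sid(comp: str, kind: str) -> str:
        return f"{comp}__{kind}"

    # blood pools
    g.add_compartment(CompartmentDef("art", "art", "blood_pool", p.arterial_volume))
    g.add_compartment(CompartmentDef("vein", "vein", "blood_pool", p.venous_volume))
    for pool, vol in (("art", p.arterial_volume), ("vein", p.venous_volume)):
        for kind in vascular_kinds:
            init = p.albumin_conc * vol if kind == "albumin" else 0.0
            g.add_species(SpeciesDef(sid(pool, kind), pool, kind, init))

    # organ compartments and species
    for o in organs:
        vas, inter = f"{o.name}_vas", f"{o.name}_int"
        g.add_compartment(CompartmentDef(vas, o.name, "vascular", o.vascular_volume))
        g.add_compartment(
            CompartmentDef(inter, o.name, "interstitial", o.interstitial_volume)
        )
        for kind in vascular_kinds:
            init = p.albumin_conc * o.vascular_volume if kind == "albumin" else 0.0
            g.add_species(SpeciesDef(sid(vas, kind), vas, kind, init))
        for kind in mobile_free:
            g.add_species(SpeciesDef(sid(inter, kind), inter, kind, 0.0))
        if albumin_on and o.name == "tumor" and options.albumin_leaks_into_tumor_interstitium:
            for kind in alb_kinds:
                g.add_species(SpeciesDef(sid(inter, kind), inter, kind, 0.0))
        if o.receptor_density > 0:
            mem, cell = f"{o.name}_mem", f"{o.name}_cell"
            # membrane receptors see interstitial concentrations; giving the
            # membrane compartment the interstitial volume makes the
            # bimolecular conversion exact
            g.add_compartment(CompartmentDef(mem, o.name, "membrane", o.interstitial_volume))
            g.add_compartment(
                CompartmentDef(cell, o.name, "intracellular", max(o.cellular_volume, 1e-6))
            )
            g.add_species(SpeciesDef(sid(mem, "receptor"), mem, "receptor", o.receptor_amount))
            g.add_species(SpeciesDef(sid(mem, "hot_bound"), mem, "hot_bound", 0.0))
            g.add_species(SpeciesDef(sid(mem, "cold_bound"), mem, "cold_bound", 0.0))
            g.add_species(SpeciesDef(sid(cell, "hot_internal"), cell, "hot_internal", 0.0))
            g.add_species(SpeciesDef(sid(cell, "cold_internal"), cell, "cold_internal", 0.0))

    # excreta
    g.add_compartment(CompartmentDef("urine", "urine", "excreta", 1.0))
    g.add_species(SpeciesDef(sid("urine", "hot_ligand"), "urine", "hot_ligand", 0.0))
    g.add_species(SpeciesDef(sid("urine", "cold_ligand"), "urine", "cold_ligand", 0.0))

    # -- reactions --
    total_flow = sum(o.plasma_flow for o in organs)

    def flow(rid, src, dst, kind, q):
        g.add_reaction(
            ReactionDef(
                rid,
                ((sid(src, kind), 1),),
                ((sid(dst, kind), 1),),
                RateLaw("flow_transport", q, (src,)),
                tag="flow",
            )
        )

    for o in organs:
        vas = f"{o.name}_vas"
        for kind in vascular_kinds:
            flow(f"flow_in__{o.name}__{kind}", "art", vas, kind, o.plasma_flow)
            flow(f"flow_out__{o.name}__{kind}", vas, "vein", kind, o.plasma_flow)
    for kind in vascular_kinds:
        flow(f"flow_return__{kind}", "vein", "art", kind, total_flow)

    def perm(rid, a, b, kind, ps):
        g.add_reaction(
            ReactionDef(
                f"{rid}_ab",
                ((sid(a, kind), 1),),
                ((sid(b, kind), 1),),
                RateLaw("permeability_transport", ps, (a,)),
                tag="permeability",
            )
        )
        g.add_reaction(
            ReactionDef(
                f"{rid}_ba",
                ((sid(b, kind), 1),),
                ((sid(a, kind), 1),),
                RateLaw("permeability_transport", ps, (b,)),
                tag="permeability",
            )
        )

    for o in organs:
        vas, inter = f"{o.name}_vas", f"{o.name}_int"
        for kind in mobile_free:
            perm(f"perm__{o.name}__{kind}", vas, inter, kind, o.permeability)
        if albumin_on and o.name == "tumor" and options.albumin_leaks_into_tumor_interstitium:
            # porous tumor vasculature: albumin and complexes leak with the
            # ligand's permeability (upper-bound assumption)
            for kind in alb_kinds:
                perm(f"perm__{o.name}__{kind}", vas, inter, kind, o.permeability)

    # receptor binding / internalization / release
    for o in organs:
        if o.receptor_density <= 0:
            continue
        inter, mem, cell = f"{o.name}_int", f"{o.name}_mem", f"{o.name}_cell"
        for hc in ("hot", "cold"):
            g.add_reaction(
                ReactionDef(
                    f"bind__{o.name}__{hc}",
                    ((sid(inter, f"{hc}_ligand"), 1), (sid(mem, "receptor"), 1)),
                    ((sid(mem, f"{hc}_bound"), 1),),
                    RateLaw("mass_action", p.k_on, (inter,)),
                    tag="binding",
                )
            )
            g.add_reaction(
                ReactionDef(
                    f"unbind__{o.name}__{hc}",
                    ((sid(mem, f"{hc}_bound"), 1),),
                    ((sid(inter, f"{hc}_ligand"), 1), (sid(mem, "receptor"), 1)),
                    RateLaw("mass_action", p.k_off),
                    tag="binding",
                )
            )
            g.add_reaction(
                ReactionDef(
                    f"internalize__{o.name}__{hc}",
                    ((sid(mem, f"{hc}_bound"), 1),),
                    ((sid(cell, f"{hc}_internal"), 1), (sid(mem, "receptor"), 1)),
                    RateLaw("mass_action", p.lambda_int),
                    tag="internalization",
                )
            )
            g.add_reaction(
                ReactionDef(
                    f"release__{o.name}__{hc}",
                    ((sid(cell, f"{hc}_internal"), 1),),
                    ((sid(inter, f"{hc}_ligand"), 1),),
                    RateLaw("mass_action", p.lambda_rel),
                    tag="release",
                )
            )

    # renal filtration of free ligand only (albumin and complexes are never
    # cleared: the kidney does not filter 70 kDa proteins)
    for hc in ("hot", "cold"):
        g.add_reaction(
            ReactionDef(
                f"renal_clearance__{hc}",
                ((sid("kidneys_vas", f"{hc}_ligand"), 1),),
                ((sid("urine", f"{hc}_ligand"), 1),),
                RateLaw("clearance", p.gfr, ("kidneys_vas",)),
                tag="clearance",
            )
        )

    # albumin binding wherever albumin coexists with free ligand
    if albumin_on:
        alb_comps = ["art", "vein"] + [f"{o.name}_vas" for o in organs]
        if options.tumor_present and options.albumin_leaks_into_tumor_interstitium:
            alb_comps.append("tumor_int")
        for comp in alb_comps:
            for hc in ("hot", "cold"):
                g.add_reaction(
                    ReactionDef(
                        f"alb_bind__{comp}__{hc}",
                        ((sid(comp, f"{hc}_ligand"), 1), (sid(comp, "albumin"), 1)),
                        ((sid(comp, f"{hc}_albumin_complex"), 1),),
                        RateLaw("mass_action", p.k_on_alb, (comp,)),
                        tag="albumin_binding",
                    )
                )
                g.add_reaction(
                    ReactionDef(
                        f"alb_unbind__{comp}__{hc}",
                        ((sid(comp, f"{hc}_albumin_complex"), 1),),
                        ((sid(comp, f"{hc}_ligand"), 1), (sid(comp, "albumin"), 1)),
                        RateLaw("mass_action", p.k_off_alb),
                        tag="albumin_binding",
                    )
                )

    # physical decay hot->cold in place, in every compartment and bound form
    decay_pairs = {
        "hot_ligand": "cold_ligand",
        "hot_bound": "cold_bound",
        "hot_internal": "cold_internal",
        "hot_albumin_complex": "cold_albumin_complex",
    }
    for s in list(g.species.values()):
        cold_kind = decay_pairs.get(s.kind)
        if cold_kind is None:
            continue
        cold_id = s.id.replace(s.kind, cold_kind)
        g.add_reaction(
            ReactionDef(
                f"decay__{s.id}",
                ((s.id, 1),),
                ((cold_id, 1),),
                RateLaw("mass_action", p.lambda_phys),
                tag="decay",
            )
        )

    return g
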