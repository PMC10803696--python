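"""Reaction-graph data model.

A :class:`ReactionGraph` is the single source of truth for a compartmental
model: compartments are containers holding several *species* (amounts in
nmol), and reactions between species carry one of four rate-law forms.  The
graph is deliberately language-neutral — it knows nothing about ODE solvers
or SBML; those live in :mod:`pbrpk.simulation` and :mod:`pbrpk.sbml`.

State variables are amounts (nmol), never concentrations.  Rate laws convert
amounts to concentrations through compartment volumes where the form requires
it, so moiety-conservation audits reduce to exact sums of state entries.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import DuplicateError, ReferentialError, ValidationError

SUBSPACES = frozenset(
    {"vascular", "interstitial", "membrane", "intracellular", "excreta", "blood_pool"}
)

SPECIES_KINDS = frozenset(
    {
        "hot_ligand",
        "cold_ligand",
        "albumin",
        "hot_albumin_complex",
        "cold_albumin_complex",
        "receptor",
        "hot_bound",
        "cold_bound",
        "hot_internal",
        "cold_internal",
        "other",  # foreign species from imported SBML
    }
)

#: species kinds that carry the radiolabel (contribute to activity)
HOT_KINDS = frozenset({"hot_ligand", "hot_bound", "hot_internal", "hot_albumin_complex"})

#: species kinds counting one ligand molecule each (hot or cold, any binding state)
LIGAND_KINDS = frozenset(
    {
        "hot_ligand",
        "cold_ligand",
        "hot_bound",
        "cold_bound",
        "hot_internal",
        "cold_internal",
        "hot_albumin_complex",
        "cold_albumin_complex",
    }
)

#: species kinds counting one albumin molecule each
ALBUMIN_KINDS = frozenset({"albumin", "hot_albumin_complex", "cold_albumin_complex"})

#: species kinds counting one receptor each
RECEPTOR_KINDS = frozenset({"receptor", "hot_bound", "cold_bound"})

RATE_FORMS = frozenset(
    {"mass_action", "flow_transport", "permeability_transport", "clearance"}
)


@dataclass(frozen=True)
class CompartmentDef:
    """A well-mixed container: one organ subspace with a fixed volume in liters."""

    id: str
    organ: str
    subspace: str
    volume: float  # L, strictly positive

    def __post_init__(self):
        if self.subspace not in SUBSPACES:
            raise ValidationError(
                f"compartment {self.id!r}: unknown subspace {self.subspace!r}"
            )
        if not (self.volume > 0) or not math.isfinite(self.volume):
            raise ValidationError(
                f"compartment {self.id!r}: volume must be finite and > 0, got {self.volume}"
            )


@dataclass(frozen=True)
class SpeciesDef:
    """One chemical species inside one compartment; amount in nmol."""

    id: str
    compartment: str
    kind: str
    initial_amount: float = 0.0  # nmol, >= 0

    def __post_init__(self):
        if self.kind not in SPECIES_KINDS:
            raise ValidationError(f"species {self.id!r}: unknown kind {self.kind!r}")
        if self.initial_amount < 0 or not math.isfinite(self.initial_amount):
            raise ValidationError(
                f"species {self.id!r}: initial_amount must be finite and >= 0"
            )


@dataclass(frozen=True)
class RateLaw:
    """One of four rate-law forms, all first- or second-order in amounts.

    ``mass_action``
        With ``volume_refs == ()`` the constant is amount-based:
        rate = k * prod(amount_i ** stoich_i); k in 1/min for unimolecular,
        1/(nmol*min) for bimolecular.  With a single volume ref (the reaction
        volume V) the constant is concentration-based:
        rate = k * V * prod((amount_i / V_comp(i)) ** stoich_i); k in 1/min
        (unimolecular) or L/(nmol*min) (bimolecular).
    ``flow_transport`` / ``permeability_transport`` / ``clearance``
        Single reactant; rate = k * amount / V_source with k a plasma flow,
        permeability-surface product or clearance in L/min.  The source
        volume is ``volume_refs[0]`` if given, else the reactant's own
        compartment.
    """

    form: str
    rate_constant: float
    volume_refs: tuple[str, ...] = ()

    def __post_init__(self):
        if self.form not in RATE_FORMS:
            raise ValidationError(f"unknown rate-law form {self.form!r}")
        if self.rate_constant < 0 or not math.isfinite(self.rate_constant):
            raise ValidationError("rate_constant must be finite and >= 0")
        if len(self.volume_refs) > 1:
            raise ValidationError("rate law references at most one volume")


@dataclass(frozen=True)
class ReactionDef:
    id: str
    reactants: tuple[tuple[str, int], ...]
    products: tuple[tuple[str, int], ...]
    rate_law: RateLaw
    tag: str = ""

    def __post_init__(self):
        for sid, st in (*self.reactants, *self.products):
            if not (isinstance(st, (int, np.integer)) and st >= 1):
                raise ValidationError(
                    f"reaction {self.id!r}: stoichiometry for {sid!r} must be a positive integer"
                )
        if not self.products and self.tag != "clearance":
            raise ValidationError(
                f"reaction {self.id!r}: empty product list allowed only for tag 'clearance'"
            )
        if not self.reactants and self.tag != "injection":
            raise ValidationError(
                f"reaction {self.id!r}: empty reactant list allowed only for tag 'injection'"
            )


@dataclass
class Diagnostic:
    """One validation finding: the offending entity and the violated rule."""

    entity: str
    rule: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.entity}: {self.rule}"


class ReactionGraph:
    """Compartments, species and reactions with deterministic insertion order.

    Insertion order defines the species/reaction indices used by the
    stoichiometry matrix, the ODE state vector and SBML export, so identical
    construction code yields bit-identical artifacts.
    """

    def __init__(self, id: str = "model"):
        self.id = id
        self.compartments: dict[str, CompartmentDef] = {}
        self.species: dict[str, SpeciesDef] = {}
        self.reactions: list[ReactionDef] = []
        self.parameters: dict[str, float] = {}
        self._reaction_ids: set[str] = set()

    # -- construction -----------------------------------------------------
    def add_compartment(self, c: CompartmentDef) -> "ReactionGraph":
        if c.id in self.compartments:
            raise DuplicateError(f"duplicate compartment id {c.id!r}")
        self.compartments[c.id] = c
        return self

    def add_species(self, s: SpeciesDef) -> "ReactionGraph":
        if s.id in self.species:
            raise DuplicateError(f"duplicate species id {s.id!r}")
        if s.compartment not in self.compartments:
            raise ReferentialError(
                f"species {s.id!r} references unknown compartment {s.compartment!r}"
            )
        self.species[s.id] = s
        return self

    def add_reaction(self, r: ReactionDef) -> "ReactionGraph":
        if r.id in self._reaction_ids:
            raise DuplicateError(f"duplicate reaction id {r.id!r}")
        for sid, _ in (*r.reactants, *r.products):
            if sid not in self.species:
                raise ReferentialError(
                    f"reaction {r.id!r} references unknown species {sid!r}"
                )
        for vref in r.rate_law.volume_refs:
            if vref not in self.compartments:
                raise ReferentialError(
                    f"reaction {r.id!r} references unknown compartment {vref!r}"
                )
        if r.rate_law.form == "mass_action" and r.rate_law.volume_refs:
            order = sum(st for _, st in r.reactants)
            if order == 2 and len(r.rate_law.volume_refs) != 1:
                raise ValidationError(
                    f"reaction {r.id!r}: bimolecular mass action needs exactly one reaction volume"
                )
        if r.rate_law.form in ("flow_transport", "permeability_transport", "clearance"):
            if len(r.reactants) != 1 or r.reactants[0][1] != 1:
                raise ValidationError(
                    f"reaction {r.id!r}: {r.rate_law.form} requires a single unit-stoichiometry reactant"
                )
        self.reactions.append(r)
        self._reaction_ids.add(r.id)
        return self

    def set_parameter(self, name: str, value: float) -> "ReactionGraph":
        self.parameters[name] = float(value)
        return self

    # -- queries ----------------------------------------------------------
    @property
    def species_ids(self) -> list[str]:
        return list(self.species)

    def species_index(self) -> dict[str, int]:
        return {sid: i for i, sid in enumerate(self.species)}

    def species_by_kind(self, *kinds: str) -> list[SpeciesDef]:
        ks = set(kinds)
        return [s for s in self.species.values() if s.kind in ks]

    def organs(self) -> list[str]:
        """Distinct organ labels in insertion order."""
        seen: dict[str, None] = {}
        for c in self.compartments.values():
            seen.setdefault(c.organ, None)
        return list(seen)

    def organ_species(self, organ: str, kinds=None) -> list[SpeciesDef]:
        comp_ids = {c.id for c in self.compartments.values() if c.organ == organ}
        if not comp_ids:
            raise ReferentialError(f"unknown organ {organ!r}")
        out = [s for s in self.species.values() if s.compartment in comp_ids]
        if kinds is not None:
            ks = set(kinds)
            out = [s for s in out if s.kind in ks]
        return out

    def stoichiometry_matrix(self) -> np.ndarray:
        """Net stoichiometry, shape (#species, #reactions); d(state)/dt = S @ rates."""
        idx = self.species_index()
        S = np.zeros((len(self.species), len(self.reactions)), dtype=int)
        for j, r in enumerate(self.reactions):
            for sid, st in r.reactants:
                S[idx[sid], j] -= st
            for sid, st in r.products:
                S[idx[sid], j] += st
        return S

    def validate(self) -> list[Diagnostic]:
        """Full invariant audit; an empty list means the graph is well-formed."""
        diags: list[Diagnostic] = []
        for c in self.compartments.values():
            if not (c.volume > 0):
                diags.append(Diagnostic(f"compartment {c.id}", "volume must be > 0"))
        for s in self.species.values():
            if s.compartment not in self.compartments:
                diags.append(
                    Diagnostic(f"species {s.id}", f"unknown compartment {s.compartment!r}")
                )
            if s.initial_amount < 0:
                diags.append(Diagnostic(f"species {s.id}", "initial_amount must be >= 0"))
            if s.kind not in SPECIES_KINDS:
                diags.append(Diagnostic(f"species {s.id}", f"unknown kind {s.kind!r}"))
        for r in self.reactions:
            for sid, _ in (*r.reactants, *r.products):
                if sid not in self.species:
                    diags.append(
                        Diagnostic(f"reaction {r.id}", f"unknown species {sid!r}")
                    )
            for vref in r.rate_law.volume_refs:
                if vref not in self.compartments:
                    diags.append(
                        Diagnostic(f"reaction {r.id}", f"unknown compartment {vref!r}")
                    )
            if r.rate_law.rate_constant < 0:
                diags.append(Diagnostic(f"reaction {r.id}", "negative rate constant"))
        return diags

    def moiety_amounts(self, state: np.ndarray, kinds) -> float:
        """Sum of amounts over all species whose kind is in *kinds*."""
        idx = self.species_index()
        ks = set(kinds)
        return float(sum(state[idx[s.id]] for s in self.species.values() if s.kind in ks))

    def initial_state(self) -> np.ndarray:
        return np.array([s.initial_amount for s in self.species.values()], dtype=float)

    def copy(self) -> "ReactionGraph":
        g = ReactionGraph(self.id)
        g.compartments = dict(self.compartments)
        g.species = dict(self.species)
        g.reactions = list(self.reactions)
        g.parameters = dict(self.parameters)
        g._reaction_ids = set(self._reaction_ids)
        return g

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"<ReactionGraph {self.id!r}: {len(self.compartments)} compartments, "
            f"{len(self.species)} species, {len(self.reactions)} reactions>"
        )


# -- module-level operation wrappers (functional spelling) -----------------


def add_compartment(graph: ReactionGraph, c: CompartmentDef) -> ReactionGraph:
    return graph.add_compartment(c)


def add_reaction(graph: ReactionGraph, r: ReactionDef) -> ReactionGraph:
    return graph.add_reaction(r)


def stoichiometry_matrix(graph: ReactionGraph) -> np.ndarray:
    return graph.stoichiometry_matrix()


def validate_graph(graph: ReactionGraph) -> list[Diagnostic]:
    return graph.validate()


# -- toy fixtures with closed-form solutions -------------------------------

TOY_KINDS = ("decay_only", "two_compartment_exchange", "minimal_binding")


def build_toy_model(kind: str) -> ReactionGraph:
    """Small fixtures with independent closed-form solutions.

    decay_only
        One blood-pool compartment ("vein" so injections resolve); hot decays
        to cold at lambda_phys = 0.01/min.  H(t) = H0 exp(-lambda t).
    two_compartment_exchange
        Linear exchange k12/k21 between two unit compartments plus decay;
        hot subsystem solvable by a 2x2 matrix exponential.
    minimal_binding
        One interstitial compartment with a finite receptor pool and
        reversible hot/cold binding; equilibrium obeys [L][R]/[LR] = K_D.
    """
    if kind == "decay_only":
        g = ReactionGraph("decay_only")
        lam = 0.01
        g.set_parameter("lambda_phys", lam)
        g.add_compartment(CompartmentDef("vein", "vein", "blood_pool", 1.0))
        g.add_species(SpeciesDef("hot", "vein", "hot_ligand", 0.0))
        g.add_species(SpeciesDef("cold", "vein", "cold_ligand", 0.0))
        g.add_reaction(
            ReactionDef(
                "decay_hot",
                (("hot", 1),),
                (("cold", 1),),
                RateLaw("mass_action", lam),
                tag="decay",
            )
        )
        return g
    if kind == "two_compartment_exchange":
        g = ReactionGraph("two_compartment_exchange")
        lam, k12, k21 = 0.01, 0.05, 0.03
        g.set_parameter("lambda_phys", lam)
        g.set_parameter("k12", k12)
        g.set_parameter("k21", k21)
        g.add_compartment(CompartmentDef("vein", "vein", "blood_pool", 1.0))
        g.add_compartment(CompartmentDef("tis", "tissue", "interstitial", 1.0))
        for comp in ("vein", "tis"):
            g.add_species(SpeciesDef(f"hot_{comp}", comp, "hot_ligand", 0.0))
            g.add_species(SpeciesDef(f"cold_{comp}", comp, "cold_ligand", 0.0))
        g.add_reaction(
            ReactionDef(
                "h_12",
                (("hot_vein", 1),),
                (("hot_tis", 1),),
                RateLaw("flow_transport", k12),
                tag="flow",
            )
        )
        g.add_reaction(
            ReactionDef(
                "h_21",
                (("hot_tis", 1),),
                (("hot_vein", 1),),
                RateLaw("flow_transport", k21),
                tag="flow",
            )
        )
        g.add_reaction(
            ReactionDef(
                "c_12",
                (("cold_vein", 1),),
                (("cold_tis", 1),),
                RateLaw("flow_transport", k12),
                tag="flow",
            )
        )
        g.add_reaction(
            ReactionDef(
                "c_21",
                (("cold_tis", 1),),
                (("cold_vein", 1),),
                RateLaw("flow_transport", k21),
                tag="flow",
            )
        )
        for comp in ("vein", "tis"):
            g.add_reaction(
                ReactionDef(
                    f"decay_{comp}",
                    ((f"hot_{comp}", 1),),
                    ((f"cold_{comp}", 1),),
                    RateLaw("mass_action", lam),
                    tag="decay",
                )
            )
        return g
    if kind == "minimal_binding":
        g = ReactionGraph("minimal_binding")
        k_on, K_D = 0.04, 0.5  # L/(nmol min), nmol/L
        g.set_parameter("lambda_phys", 0.0)
        g.set_parameter("k_on", k_on)
        g.set_parameter("K_D", K_D)
        g.add_compartment(CompartmentDef("int", "tissue", "interstitial", 1.0))
        g.add_species(SpeciesDef("hot", "int", "hot_ligand", 1.0))
        g.add_species(SpeciesDef("cold", "int", "cold_ligand", 0.0))
        g.add_species(SpeciesDef("receptor", "int", "receptor", 5.0))
        g.add_species(SpeciesDef("hot_bound", "int", "hot_bound", 0.0))
        g.add_species(SpeciesDef("cold_bound", "int", "cold_bound", 0.0))
        for lig in ("hot", "cold"):
            g.add_reaction(
                ReactionDef(
                    f"bind_{lig}",
                    ((lig, 1), ("receptor", 1)),
                    ((f"{lig}_bound", 1),),
                    RateLaw("mass_action", k_on, ("int",)),
                    tag="binding",
                )
            )
            g.add_reaction(
                ReactionDef(
                    f"unbind_{lig}",
                    ((f"{lig}_bound", 1),),
                    ((lig, 1), ("receptor", 1)),
                    RateLaw("mass_action", k_on * K_D),
                    tag="binding",
                )
            )
        return g
    raise ValidationError(f"unknown toy model kind {kind!r}; expected one of {TOY_KINDS}")
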