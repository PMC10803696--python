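"""Human-editable YAML serialization of reaction graphs and run configs."""

from __future__ import annotations

import yaml

from .graph import CompartmentDef, RateLaw, ReactionDef, ReactionGraph, SpeciesDef
from .simulation import InjectionSchedule, SolverSettings


def graph_to_dict(graph: ReactionGraph) -> dict:
    return {
        "id": graph.id,
        "compartments": [
            {"id": c.id, "organ": c.organ, "subspace": c.subspace, "volume_L": c.volume}
            for c in graph.compartments.values()
        ],
        "species": [
            {
                "id": s.id,
                "compartment": s.compartment,
                "kind": s.kind,
                "initial_amount_nmol": s.initial_amount,
            }
            for s in graph.species.values()
        ],
        "reactions": [
            {
                "id": r.id,
                "reactants": [[sp, st] for sp, st in r.reactants],
                "products": [[sp, st] for sp, st in r.products],
                "rate_law": {
                    "form": r.rate_law.form,
                    "rate_constant": r.rate_law.rate_constant,
                    "volume_refs": list(r.rate_law.volume_refs),
                },
                "tag": r.tag,
            }
            for r in graph.reactions
        ],
        "parameters": dict(graph.parameters),
    }


def graph_from_dict(doc: dict) -> ReactionGraph:
    g = ReactionGraph(doc.get("id", "model"))
    for c in doc.get("compartments", []):
        g.add_compartment(
            CompartmentDef(c["id"], c["organ"], c["subspace"], float(c["volume_L"]))
        )
    for s in doc.get("species", []):
        g.add_species(
            SpeciesDef(
                s["id"], s["compartment"], s["kind"], float(s.get("initial_amount_nmol", 0.0))
            )
        )
    for name, value in doc.get("parameters", {}).items():
        g.set_parameter(name, float(value))
    for r in doc.get("reactions", []):
        law = r["rate_law"]
        g.add_reaction(
            ReactionDef(
                r["id"],
                tuple((sp, int(st)) for sp, st in r.get("reactants", [])),
                tuple((sp, int(st)) for sp, st in r.get("products", [])),
                RateLaw(
                    law["form"],
                    float(law["rate_constant"]),
                    tuple(law.get("volume_refs", [])),
                ),
                tag=r.get("tag", ""),
            )
        )
    return g


def save_graph(graph: ReactionGraph, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(graph_to_dict(graph), fh, sort_keys=False)


def load_graph(path) -> ReactionGraph:
    with open(path) as fh:
        return graph_from_dict(yaml.safe_load(fh))


def schedule_to_dict(s: InjectionSchedule) -> dict:
    return {
        "hot_total_nmol": s.hot_total,
        "cold_total_nmol": s.cold_total,
        "n_injections": s.n_injections,
        "interval_min": s.interval,
        **({"hot_fractions": list(s.hot_fractions)} if s.hot_fractions else {}),
        **({"cold_fractions": list(s.cold_fractions)} if s.cold_fractions else {}),
    }


def schedule_from_dict(doc: dict) -> InjectionSchedule:
    return InjectionSchedule(
        hot_total=float(doc["hot_total_nmol"]),
        cold_total=float(doc["cold_total_nmol"]),
        n_injections=int(doc.get("n_injections", 1)),
        interval=float(doc.get("interval_min", 0.0)),
        hot_fractions=tuple(doc["hot_fractions"]) if "hot_fractions" in doc else None,
        cold_fractions=tuple(doc["cold_fractions"]) if "cold_fractions" in doc else None,
    )


def settings_to_dict(s: SolverSettings) -> dict:
    return {
        "rtol": s.rtol,
        "atol_nmol": s.atol,
        "t_end_min": s.t_end,
        "n_grid": s.n_grid,
        "method": s.method,
    }


def settings_from_dict(doc: dict) -> SolverSettings:
    return SolverSettings(
        rtol=float(doc.get("rtol", 1e-8)),
        atol=float(doc.get("atol_nmol", 1e-12)),
        t_end=float(doc.get("t_end_min", 50_000.0)),
        n_grid=int(doc.get("n_grid", 400)),
        method=str(doc.get("method", "BDF")),
    )
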