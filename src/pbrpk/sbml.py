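"""SBML Level 3 Version 2 (core) interchange for reaction graphs.

The writer emits a deterministic document: element order follows graph
insertion order, numbers are serialized with ``repr`` (shortest float
round-trip), and kinetic laws are written in the amount-based monomial
form produced by :func:`pbrpk.simulation.amount_based_monomial` — the same
reduction the ODE compiler uses — so an exported model integrates
identically to the in-memory one, and export∘import∘export is byte-stable.

The reader accepts any core document restricted to the constructs the
data model can represent (compartments, amount-based species, reversible
flag false, product-of-amounts kinetic laws, bolus events of the writer's
shape).  Rules, constraints, function definitions, initial assignments
and delays raise :class:`UnsupportedSBMLError` naming the construct.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from xml.etree import ElementTree as ET
from xml.sax.saxutils import escape, quoteattr

from .errors import UnsupportedSBMLError, ValidationError
from .graph import (
    SPECIES_KINDS,
    CompartmentDef,
    RateLaw,
    ReactionDef,
    ReactionGraph,
    SpeciesDef,
)
from .simulation import InjectionSchedule, amount_based_monomial, find_injection_targets

SBML_NS = "http://www.sbml.org/sbml/level3/version2/core"
MATHML_NS = "http://www.w3.org/1998/Math/MathML"
TIME_URL = "http://www.sbml.org/sbml/symbols/time"


@dataclass(frozen=True)
class SBMLDocumentHandle:
    level: int
    version: int
    model_id: str
    path: str
    sha256: str


def _num(x: float) -> str:
    return repr(float(x))


def export_sbml(
    graph: ReactionGraph, path, schedule: InjectionSchedule | None = None
) -> SBMLDocumentHandle:
    """Write *graph* (optionally with bolus events) as SBML L3V2 core."""
    diags = graph.validate()
    if diags:
        raise ValidationError(
            "refusing to export an invalid graph: " + "; ".join(map(str, diags))
        )
    w = []
    w.append('<?xml version="1.0" encoding="UTF-8"?>')
    w.append(f'<sbml xmlns="{SBML_NS}" level="3" version="2">')
    w.append(f'  <model id={quoteattr(_sid(graph.id))} name={quoteattr(graph.id)}>')

    w.append("    <listOfCompartments>")
    for c in graph.compartments.values():
        w.append(
            f'      <compartment id={quoteattr(c.id)} name={quoteattr(f"{c.organ}|{c.subspace}")}'
            f' spatialDimensions="3" size="{_num(c.volume)}" constant="true"/>'
        )
    w.append("    </listOfCompartments>")

    w.append("    <listOfSpecies>")
    for s in graph.species.values():
        w.append(
            f'      <species id={quoteattr(s.id)} name={quoteattr(s.kind)}'
            f' compartment={quoteattr(s.compartment)} initialAmount="{_num(s.initial_amount)}"'
            f' hasOnlySubstanceUnits="true" boundaryCondition="false" constant="false"/>'
        )
    w.append("    </listOfSpecies>")

    if graph.parameters:
        w.append("    <listOfParameters>")
        for name, value in graph.parameters.items():
            w.append(
                f'      <parameter id={quoteattr(_sid(name))} value="{_num(value)}" constant="true"/>'
            )
        w.append("    </listOfParameters>")

    w.append("    <listOfReactions>")
    for r in graph.reactions:
        coef, sids = amount_based_monomial(graph, r)
        w.append(
            f'      <reaction id={quoteattr(_sid(r.id))} name={quoteattr(r.tag)} reversible="false">'
        )
        if r.reactants:
            w.append("        <listOfReactants>")
            for sp, st in r.reactants:
                w.append(
                    f'          <speciesReference species={quoteattr(sp)} stoichiometry="{st}" constant="true"/>'
                )
            w.append("        </listOfReactants>")
        if r.products:
            w.append("        <listOfProducts>")
            for sp, st in r.products:
                w.append(
                    f'          <speciesReference species={quoteattr(sp)} stoichiometry="{st}" constant="true"/>'
                )
            w.append("        </listOfProducts>")
        w.append("        <kineticLaw>")
        w.append(f'          <math xmlns="{MATHML_NS}">')
        w.append("            <apply>")
        w.append("              <times/>")
        w.append("              <ci> k </ci>")
        for sp in sids:
            w.append(f"              <ci> {escape(sp)} </ci>")
        w.append("            </apply>")
        w.append("          </math>")
        w.append("          <listOfLocalParameters>")
        w.append(f'            <localParameter id="k" value="{_num(coef)}"/>')
        w.append("          </listOfLocalParameters>")
        w.append("        </kineticLaw>")
        w.append("      </reaction>")
    w.append("    </listOfReactions>")

    if schedule is not None:
        hot_t, cold_t = find_injection_targets(graph)
        w.append("    <listOfEvents>")
        for i, (t, hot, cold) in enumerate(schedule.bolus_amounts()):
            w.append(
                f'      <event id="bolus_{i}" useValuesFromTriggerTime="true">'
            )
            w.append('        <trigger initialValue="false" persistent="true">')
            w.append(f'          <math xmlns="{MATHML_NS}">')
            w.append("            <apply>")
            w.append("              <geq/>")
            w.append(
                f'              <csymbol encoding="text" definitionURL="{TIME_URL}"> t </csymbol>'
            )
            w.append(f"              <cn> {_num(t)} </cn>")
            w.append("            </apply>")
            w.append("          </math>")
            w.append("        </trigger>")
            w.append("        <listOfEventAssignments>")
            for target, amt in ((hot_t, hot), (cold_t, cold)):
                w.append(f"          <eventAssignment variable={quoteattr(target)}>")
                w.append(f'            <math xmlns="{MATHML_NS}">')
                w.append("              <apply>")
                w.append("                <plus/>")
                w.append(f"                <ci> {escape(target)} </ci>")
                w.append(f"                <cn> {_num(amt)} </cn>")
                w.append("              </apply>")
                w.append("            </math>")
                w.append("          </eventAssignment>")
            w.append("        </listOfEventAssignments>")
            w.append("      </event>")
        w.append("    </listOfEvents>")

    w.append("  </model>")
    w.append("</sbml>")
    text = "\n".join(w) + "\n"

    check_document_text(text)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(text)
    return SBMLDocumentHandle(
        level=3,
        version=2,
        model_id=_sid(graph.id),
        path=str(path),
        sha256=hashlib.sha256(text.encode()).hexdigest(),
    )


def _sid(raw: str) -> str:
    out = "".join(ch if (ch.isalnum() or ch == "_") else "_" for ch in raw)
    if not out or out[0].isdigit():
        out = "_" + out
    return out


def _tag(el) -> str:
    return el.tag.rsplit("}", 1)[-1]


_UNSUPPORTED_LISTS = {
    "listOfRules": "rule",
    "listOfConstraints": "constraint",
    "listOfFunctionDefinitions": "functionDefinition",
    "listOfInitialAssignments": "initialAssignment",
}


def check_document_text(text: str) -> None:
    """Structural consistency check on a serialized document.

    Verifies well-formed XML, unique ids, and that every compartment /
    species reference resolves; raises :class:`ValidationError` otherwise.
    """
    root = ET.fromstring(text)
    model = root.find(f"{{{SBML_NS}}}model")
    if model is None:
        raise ValidationError("SBML document has no <model> element")
    comp_ids, sp_ids = set(), set()
    for el in model.iter():
        t = _tag(el)
        if t == "compartment":
            cid = el.get("id")
            if cid in comp_ids:
                raise ValidationError(f"duplicate compartment id {cid!r}")
            comp_ids.add(cid)
        elif t == "species":
            sid = el.get("id")
            if sid in sp_ids:
                raise ValidationError(f"duplicate species id {sid!r}")
            sp_ids.add(sid)
    for el in model.iter():
        t = _tag(el)
        if t == "species" and el.get("compartment") not in comp_ids:
            raise ValidationError(
                f"species {el.get('id')!r} references unknown compartment"
            )
        if t == "speciesReference" and el.get("species") not in sp_ids:
            raise ValidationError(
                f"speciesReference to unknown species {el.get('species')!r}"
            )


def import_sbml(path) -> ReactionGraph:
    """Read a core SBML document into a :class:`ReactionGraph`.

    Kinetic laws must be products of one constant and the reactant
    amounts; they are imported as amount-based mass-action laws (this is
    lossless for documents written by :func:`export_sbml`).  Bolus events
    of the writer's shape are returned on ``graph.injection_events`` as a
    list of (time, {species: added amount}).
    """
    tree = ET.parse(path)
    root = tree.getroot()
    model = root.find(f"{{{SBML_NS}}}model")
    if model is None:
        raise UnsupportedSBMLError("document without a core <model>")
    for list_tag, construct in _UNSUPPORTED_LISTS.items():
        el = model.find(f"{{{SBML_NS}}}{list_tag}")
        if el is not None and len(el):
            raise UnsupportedSBMLError(construct)

    g = ReactionGraph(model.get("name") or model.get("id") or "model")

    for el in model.iterfind(f"{{{SBML_NS}}}listOfCompartments/{{{SBML_NS}}}compartment"):
        name = el.get("name") or ""
        if "|" in name:
            organ, subspace = name.split("|", 1)
        else:
            organ, subspace = el.get("id"), "vascular"
        size = el.get("size")
        if size is None:
            raise UnsupportedSBMLError("compartment without a size")
        g.add_compartment(CompartmentDef(el.get("id"), organ, subspace, float(size)))

    for el in model.iterfind(f"{{{SBML_NS}}}listOfSpecies/{{{SBML_NS}}}species"):
        if el.get("boundaryCondition") == "true" or el.get("constant") == "true":
            raise UnsupportedSBMLError("boundary/constant species")
        kind = el.get("name") or ""
        if kind not in SPECIES_KINDS:
            kind = "other"
        amt = el.get("initialAmount")
        if amt is None:
            raise UnsupportedSBMLError("species without initialAmount")
        g.add_species(SpeciesDef(el.get("id"), el.get("compartment"), kind, float(amt)))

    params: dict[str, float] = {}
    for el in model.iterfind(f"{{{SBML_NS}}}listOfParameters/{{{SBML_NS}}}parameter"):
        value = el.get("value")
        if value is not None:
            params[el.get("id")] = float(value)
            g.set_parameter(el.get("id"), float(value))

    for el in model.iterfind(f"{{{SBML_NS}}}listOfReactions/{{{SBML_NS}}}reaction"):
        rid = el.get("id")
        reactants = [
            (sr.get("species"), int(float(sr.get("stoichiometry", "1"))))
            for sr in el.iterfind(
                f"{{{SBML_NS}}}listOfReactants/{{{SBML_NS}}}speciesReference"
            )
        ]
        products = [
            (sr.get("species"), int(float(sr.get("stoichiometry", "1"))))
            for sr in el.iterfind(
                f"{{{SBML_NS}}}listOfProducts/{{{SBML_NS}}}speciesReference"
            )
        ]
        kl = el.find(f"{{{SBML_NS}}}kineticLaw")
        if kl is None:
            raise UnsupportedSBMLError(f"reaction {rid!r} without a kineticLaw")
        local = {
            lp.get("id"): float(lp.get("value"))
            for lp in kl.iterfind(
                f"{{{SBML_NS}}}listOfLocalParameters/{{{SBML_NS}}}localParameter"
            )
        }
        coef, sids = _parse_monomial(kl, {**params, **local}, set(g.species))
        expect = []
        for sp, st in reactants:
            expect.extend([sp] * st)
        if sorted(sids) != sorted(expect):
            raise UnsupportedSBMLError(
                f"kinetic law of reaction {rid!r} is not mass action in its reactants"
            )
        tag = el.get("name") or ""
        g.add_reaction(
            ReactionDef(
                rid,
                tuple(reactants),
                tuple(products),
                RateLaw("mass_action", coef),
                tag=tag,
            )
        )

    events = []
    ev_list = model.find(f"{{{SBML_NS}}}listOfEvents")
    if ev_list is not None:
        for ev in ev_list:
            if ev.find(f"{{{SBML_NS}}}delay") is not None:
                raise UnsupportedSBMLError("event delay")
            events.append(_parse_bolus_event(ev, set(g.species)))
    g.injection_events = events
    return g


def _math_apply(parent):
    math = parent.find(f"{{{MATHML_NS}}}math")
    if math is None:
        raise UnsupportedSBMLError("missing <math>")
    apply_el = math.find(f"{{{MATHML_NS}}}apply")
    if apply_el is None:
        raise UnsupportedSBMLError("non-apply math expression")
    return apply_el


def _parse_monomial(kl, constants: dict[str, float], species_ids: set[str]):
    apply_el = _math_apply(kl)
    children = list(apply_el)
    if not children or _tag(children[0]) != "times":
        # a bare <ci> or single-factor law is not emitted by the writer but
        # a product with one factor is still a monomial; anything else is not
        raise UnsupportedSBMLError("kinetic law is not a product of factors")
    coef = 1.0
    sids: list[str] = []
    for el in children[1:]:
        t = _tag(el)
        if t == "ci":
            name = (el.text or "").strip()
            if name in species_ids:
                sids.append(name)
            elif name in constants:
                coef *= constants[name]
            else:
                raise UnsupportedSBMLError(f"unknown symbol {name!r} in kinetic law")
        elif t == "cn":
            coef *= float((el.text or "0").strip())
        else:
            raise UnsupportedSBMLError(f"math element <{t}> in kinetic law")
    return coef, sids


def _parse_bolus_event(ev, species_ids: set[str]):
    trig = ev.find(f"{{{SBML_NS}}}trigger")
    if trig is None:
        raise UnsupportedSBMLError("event without trigger")
    apply_el = _math_apply(trig)
    children = list(apply_el)
    if len(children) != 3 or _tag(children[0]) != "geq" or _tag(children[1]) != "csymbol":
        raise UnsupportedSBMLError("event trigger (expected time >= constant)")
    t = float((children[2].text or "0").strip())
    deltas: dict[str, float] = {}
    for ea in ev.iterfind(
        f"{{{SBML_NS}}}listOfEventAssignments/{{{SBML_NS}}}eventAssignment"
    ):
        var = ea.get("variable")
        if var not in species_ids:
            raise UnsupportedSBMLError("event assignment to a non-species variable")
        apply_el = _math_apply(ea)
        children = list(apply_el)
        if (
            len(children) != 3
            or _tag(children[0]) != "plus"
            or _tag(children[1]) != "ci"
            or (children[1].text or "").strip() != var
            or _tag(children[2]) != "cn"
        ):
            raise UnsupportedSBMLError("event assignment (expected var + constant)")
        deltas[var] = float((children[2].text or "0").strip())
    return (t, deltas)
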