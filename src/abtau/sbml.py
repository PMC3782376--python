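"""SBML Level 2 read/write for reaction networks with timed events.

A focused reader/writer for the SBML dialect this model family uses: a single
compartment, species with integer initial amounts, global parameters,
irreversible reactions with MathML kinetic laws, and events triggered by
``time >= T`` whose assignments set species to constants.

Kinetic laws are pattern-matched into the package's rate-law kinds
(mass-action products and the saturating Hill form); anything else is retained
as an interpreted expression tree so that simulation is never blocked by
classification. Unsupported SBML constructs (rules, function definitions,
compartment-size kinetics) raise :class:`UnsupportedConstructError` naming the
construct. Round-tripping a network through a file reproduces it exactly.
"""

from __future__ import annotations

import math

from lxml import etree

from .model import PARAM_ALIASES, SPECIES_RENAMES, canonical_param
from .network import (Parameter, RateLaw, Reaction, ReactionNetwork,
                      Saturation, Species, TimedEvent, validate_network)

__all__ = ["import_sbml", "export_sbml", "diff_networks", "SbmlError",
           "UnsupportedConstructError", "reference_model_path",
           "load_reference_model"]

SBML_NS = "http://www.sbml.org/sbml/level2/version4"
MATHML_NS = "http://www.w3.org/1998/Math/MathML"
TIME_URL = "http://www.sbml.org/sbml/symbols/time"


class SbmlError(ValueError):
    """File does not parse or is not usable SBML."""


class UnsupportedConstructError(SbmlError):
    """The file uses an SBML construct outside the supported dialect."""


def _local(tag) -> str:
    return etree.QName(tag).localname if isinstance(tag, str) else ""


def _children(el, name):
    return [c for c in el if isinstance(c.tag, str) and _local(c.tag) == name]


def _child(el, name):
    found = _children(el, name)
    return found[0] if found else None


# ---------------------------------------------------------------------------
# MathML <-> expression trees
# ---------------------------------------------------------------------------

_OPS = {"plus": "+", "minus": "-", "times": "*", "divide": "/", "power": "pow"}


def _parse_math(el, species: set[str], params: set[str]) -> tuple:
    name = _local(el.tag)
    if name == "math":
        kids = [c for c in el if isinstance(c.tag, str)]
        if len(kids) != 1:
            raise UnsupportedConstructError("math element with multiple children")
        return _parse_math(kids[0], species, params)
    if name == "cn":
        return ("num", float(el.text.strip()))
    if name == "ci":
        ident = el.text.strip()
        if ident in species:
            return ("species", ident)
        if ident in params:
            return ("param", ident)
        raise SbmlError(f"kinetic law references unknown symbol {ident!r}")
    if name == "csymbol":
        if el.get("definitionURL", "") == TIME_URL:
            return ("time",)
        raise UnsupportedConstructError(f"csymbol {el.get('definitionURL')!r}")
    if name == "apply":
        kids = [c for c in el if isinstance(c.tag, str)]
        opname = _local(kids[0].tag)
        if opname not in _OPS:
            raise UnsupportedConstructError(f"MathML operator <{opname}>")
        args = [_parse_math(k, species, params) for k in kids[1:]]
        return (_OPS[opname], *args)
    raise UnsupportedConstructError(f"MathML element <{name}>")


def _math_el(expr: tuple) -> etree._Element:
    M = "{%s}" % MATHML_NS
    op = expr[0]
    if op == "num":
        el = etree.Element(M + "cn")
        v = expr[1]
        el.text = str(int(v)) if float(v).is_integer() and abs(v) < 1e15 else repr(float(v))
        if "." not in el.text and "e" not in el.text:
            el.set("type", "integer")
        return el
    if op in ("param", "species"):
        el = etree.Element(M + "ci")
        el.text = " " + expr[1] + " "
        return el
    if op == "time":
        el = etree.Element(M + "csymbol")
        el.set("encoding", "text")
        el.set("definitionURL", TIME_URL)
        el.text = " time "
        return el
    names = {"+": "plus", "-": "minus", "*": "times", "/": "divide",
             "pow": "power", ">=": "geq"}
    el = etree.Element(M + "apply")
    el.append(etree.Element(M + names[op]))
    for arg in expr[1:]:
        el.append(_math_el(arg))
    return el


def _law_to_expr(law: RateLaw) -> tuple:
    if law.kind == "expression":
        return law.expression
    factors: list[tuple] = [("param", law.rate_constant)]
    factors += [("species", s) for s in law.reactant_factors]
    if law.kind == "saturating":
        s, h = law.saturation.substrate, law.saturation.half_param
        factors.append(("/", ("species", s), ("+", ("species", s), ("param", h))))
    return factors[0] if len(factors) == 1 else ("*", *factors)


def _flatten_times(expr: tuple) -> list[tuple] | None:
    if expr[0] == "*":
        out: list[tuple] = []
        for child in expr[1:]:
            sub = _flatten_times(child)
            if sub is None:
                return None
            out.extend(sub)
        return out
    return [expr]


def _expr_to_law(expr: tuple) -> RateLaw:
    """Classify an expression: mass-action product, saturating form, or keep
    as interpreted expression."""
    factors = _flatten_times(expr)
    if factors is not None:
        params = [f[1] for f in factors if f[0] == "param"]
        species = [f[1] for f in factors if f[0] == "species"]
        ratios = [f for f in factors if f[0] == "/"]
        others = [f for f in factors
                  if f[0] not in ("param", "species", "/")]
        if len(params) == 1 and not others:
            if not ratios:
                return RateLaw("mass_action", params[0], tuple(species))
            if len(ratios) == 1:
                num, den = ratios[0][1], ratios[0][2]
                if (num[0] == "species" and den[0] == "+" and len(den) == 3):
                    terms = {den[1], den[2]}
                    if num in terms:
                        other = (terms - {num}).pop()
                        if other[0] == "param":
                            return RateLaw("saturating", params[0], tuple(species),
                                           Saturation(num[1], other[1]))
    return RateLaw("expression", expression=expr)


# ---------------------------------------------------------------------------
# import
# ---------------------------------------------------------------------------

def import_sbml(path) -> ReactionNetwork:
    """Read an SBML Level 2 file into a :class:`ReactionNetwork`.

    Legacy species names and parameter spellings are normalised through the
    documented alias maps so imports compare cleanly against programmatic
    builds. Initial amounts must be integers (the stochastic engine's state
    space); events must trigger on ``time >= T`` with constant assignments.
    """
    try:
        tree = etree.parse(str(path))
    except (etree.XMLSyntaxError, OSError) as e:
        raise SbmlError(f"cannot parse {path}: {e}") from e
    root = tree.getroot()
    if _local(root.tag) != "sbml":
        raise SbmlError(f"{path}: root element is <{_local(root.tag)}>, not <sbml>")
    level = root.get("level", "2")
    if level != "2":
        raise UnsupportedConstructError(f"SBML level {level} (only level 2 supported)")
    model = _child(root, "model")
    if model is None:
        raise SbmlError(f"{path}: no <model> element")

    for bad in ("listOfRules", "listOfFunctionDefinitions", "listOfConstraints",
                "listOfInitialAssignments"):
        if _child(model, bad) is not None:
            raise UnsupportedConstructError(bad)

    net = ReactionNetwork(name=model.get("id") or model.get("name") or "model")

    los = _child(model, "listOfSpecies")
    for sp in _children(los, "species") if los is not None else []:
        amt = sp.get("initialAmount")
        if amt is None:
            amt = sp.get("initialConcentration", "0")
        value = float(amt)
        if not float(value).is_integer():
            raise SbmlError(f"species {sp.get('id')!r}: non-integer initial amount {value}")
        sid = SPECIES_RENAMES.get(sp.get("id"), sp.get("id"))
        net.species.append(Species(sid, value, sp.get("name") or ""))

    lop = _child(model, "listOfParameters")
    for par in _children(lop, "parameter") if lop is not None else []:
        net.parameters.append(Parameter(canonical_param(par.get("id")),
                                        float(par.get("value", "0")),
                                        provenance="imported"))

    species_ids = {s.id for s in net.species}
    raw_species = set(species_ids) | set(SPECIES_RENAMES)
    param_ids = {p.id for p in net.parameters} | set(PARAM_ALIASES)

    lor = _child(model, "listOfReactions")
    for rx in _children(lor, "reaction") if lor is not None else []:
        rid = rx.get("id")
        reactants, products = {}, {}
        for side, store in (("listOfReactants", reactants), ("listOfProducts", products)):
            lo = _child(rx, side)
            for ref in _children(lo, "speciesReference") if lo is not None else []:
                st = float(ref.get("stoichiometry", "1"))
                if not st.is_integer() or st <= 0:
                    raise SbmlError(f"reaction {rid!r}: non-integer stoichiometry {st}")
                sid = SPECIES_RENAMES.get(ref.get("species"), ref.get("species"))
                store[sid] = store.get(sid, 0) + int(st)
        modifiers = []
        lom = _child(rx, "listOfModifiers")
        for ref in _children(lom, "modifierSpeciesReference") if lom is not None else []:
            modifiers.append(SPECIES_RENAMES.get(ref.get("species"), ref.get("species")))
        kl = _child(rx, "kineticLaw")
        if kl is None:
            raise UnsupportedConstructError(f"reaction {rid!r} without kineticLaw")
        if _child(kl, "listOfParameters") is not None:
            raise UnsupportedConstructError(
                f"local parameters in kineticLaw of {rid!r}")
        math = _child(kl, "math")
        expr = _parse_math(math, raw_species, param_ids)
        expr = _canonicalise_ids(expr)
        net.reactions.append(Reaction(rid, reactants, products,
                                      tuple(modifiers), _expr_to_law(expr)))

    loe = _child(model, "listOfEvents")
    for ev in _children(loe, "event") if loe is not None else []:
        trig = _child(ev, "trigger")
        texpr = _parse_math(_child(trig, "math"), raw_species, param_ids)
        # supported trigger shape: time >= T (or T <= time, written either way)
        if not (texpr[0] == ">=" and len(texpr) == 3):
            raise UnsupportedConstructError(f"event trigger {texpr!r}")
        left, right = texpr[1], texpr[2]
        if left == ("time",) and right[0] == "num":
            ttime = float(right[1])
        elif right == ("time",) and left[0] == "num":
            ttime = float(left[1])
        else:
            raise UnsupportedConstructError(f"event trigger {texpr!r}")
        assignments = {}
        loa = _child(ev, "listOfEventAssignments")
        for ea in _children(loa, "eventAssignment") if loa is not None else []:
            vexpr = _parse_math(_child(ea, "math"), raw_species, param_ids)
            if vexpr[0] != "num":
                raise UnsupportedConstructError("non-constant event assignment")
            var = SPECIES_RENAMES.get(ea.get("variable"), ea.get("variable"))
            assignments[var] = float(vexpr[1])
        net.events.append(TimedEvent(ttime, assignments))
    return net


def _canonicalise_ids(expr: tuple) -> tuple:
    op = expr[0]
    if op == "param":
        return ("param", canonical_param(expr[1]))
    if op == "species":
        return ("species", SPECIES_RENAMES.get(expr[1], expr[1]))
    if op in ("num", "time"):
        return expr
    return (op, *(_canonicalise_ids(c) for c in expr[1:]))


# The trigger comparison operators are parsed through the generic MathML path,
# so register them as pass-through "operators".
_OPS.setdefault("geq", ">=")
_OPS.setdefault("gt", ">=")


# ---------------------------------------------------------------------------
# export
# ---------------------------------------------------------------------------

def _num(v: float) -> str:
    return repr(float(v))


def export_sbml(net: ReactionNetwork, path) -> None:
    """Write a valid SBML L2V4 file; refuses to write an invalid network."""
    violations = validate_network(net)
    if violations:
        raise ValueError(f"refusing to export invalid network: {violations[0]}")
    S = "{%s}" % SBML_NS
    nsmap = {None: SBML_NS}
    root = etree.Element(S + "sbml", nsmap=nsmap)
    root.set("level", "2")
    root.set("version", "4")
    model = etree.SubElement(root, S + "model")
    model.set("id", "".join(ch if ch.isalnum() or ch == "_" else "_"
                            for ch in (net.name or "model")))

    loc = etree.SubElement(model, S + "listOfCompartments")
    comp = etree.SubElement(loc, S + "compartment")
    comp.set("id", "cell")
    comp.set("size", "1")

    if net.species:
        los = etree.SubElement(model, S + "listOfSpecies")
        for sp in net.species:
            el = etree.SubElement(los, S + "species")
            el.set("id", sp.id)
            if sp.description:
                el.set("name", sp.description)
            el.set("compartment", "cell")
            el.set("initialAmount", _num(sp.initial_amount))
            el.set("hasOnlySubstanceUnits", "true")
    if net.parameters:
        lop = etree.SubElement(model, S + "listOfParameters")
        for par in net.parameters:
            el = etree.SubElement(lop, S + "parameter")
            el.set("id", par.id)
            el.set("value", _num(par.value))
    if net.reactions:
        lor = etree.SubElement(model, S + "listOfReactions")
        for rxn in net.reactions:
            el = etree.SubElement(lor, S + "reaction")
            el.set("id", rxn.id)
            el.set("reversible", "false")
            for side, items in (("listOfReactants", rxn.reactants),
                                ("listOfProducts", rxn.products)):
                if items:
                    lo = etree.SubElement(el, S + side)
                    for sid, st in items.items():
                        ref = etree.SubElement(lo, S + "speciesReference")
                        ref.set("species", sid)
                        ref.set("stoichiometry", str(int(st)))
            if rxn.modifiers:
                lom = etree.SubElement(el, S + "listOfModifiers")
                for sid in rxn.modifiers:
                    ref = etree.SubElement(lom, S + "modifierSpeciesReference")
                    ref.set("species", sid)
            kl = etree.SubElement(el, S + "kineticLaw")
            math = etree.SubElement(kl, "{%s}math" % MATHML_NS,
                                    nsmap={None: MATHML_NS})
            math.append(_math_el(_law_to_expr(rxn.rate_law)))
    if net.events:
        loe = etree.SubElement(model, S + "listOfEvents")
        for i, ev in enumerate(net.events):
            el = etree.SubElement(loe, S + "event")
            el.set("id", f"event_{i}")
            trig = etree.SubElement(el, S + "trigger")
            math = etree.SubElement(trig, "{%s}math" % MATHML_NS,
                                        nsmap={None: MATHML_NS})
            math.append(_math_el((">=", ("time",), ("num", ev.trigger_time))))
            loa = etree.SubElement(el, S + "listOfEventAssignments")
            for sid, val in ev.assignments.items():
                ea = etree.SubElement(loa, S + "eventAssignment")
                ea.set("variable", sid)
                m2 = etree.SubElement(ea, "{%s}math" % MATHML_NS,
                                      nsmap={None: MATHML_NS})
                m2.append(_math_el(("num", val)))

    etree.ElementTree(root).write(str(path), xml_declaration=True,
                                  encoding="UTF-8", pretty_print=True)




# ---------------------------------------------------------------------------
# structural diff
# ---------------------------------------------------------------------------

def _law_signature(law: RateLaw):
    if law is None:
        return None
    if law.kind == "expression":
        return ("expression", law.expression)
    sig = (law.kind, law.rate_constant, tuple(sorted(law.reactant_factors)))
    if law.saturation is not None:
        sig += ((law.saturation.substrate, law.saturation.half_param),)
    return sig


def diff_networks(a: ReactionNetwork, b: ReactionNetwork,
                  rel_tol: float = 1e-9) -> list[str]:
    """Structured difference report; empty iff the networks are semantically
    equal up to element ordering and the documented alias maps."""
    out: list[str] = []

    sa = {s.id: s for s in a.species}
    sb = {s.id: s for s in b.species}
    for sid in sorted(set(sa) - set(sb)):
        out.append(f"species {sid!r} only in first")
    for sid in sorted(set(sb) - set(sa)):
        out.append(f"species {sid!r} only in second")
    for sid in sorted(set(sa) & set(sb)):
        if not math.isclose(sa[sid].initial_amount, sb[sid].initial_amount,
                            rel_tol=rel_tol, abs_tol=1e-12):
            out.append(f"species {sid!r}: initial amount "
                       f"{sa[sid].initial_amount} != {sb[sid].initial_amount}")

    pa = {p.id: p.value for p in a.parameters}
    pb = {p.id: p.value for p in b.parameters}
    for pid in sorted(set(pa) - set(pb)):
        out.append(f"parameter {pid!r} only in first")
    for pid in sorted(set(pb) - set(pa)):
        out.append(f"parameter {pid!r} only in second")
    for pid in sorted(set(pa) & set(pb)):
        if not math.isclose(pa[pid], pb[pid], rel_tol=rel_tol, abs_tol=0.0):
            out.append(f"parameter {pid!r}: value {pa[pid]!r} != {pb[pid]!r}")

    ra = {r.id: r for r in a.reactions}
    rb = {r.id: r for r in b.reactions}
    for rid in sorted(set(ra) - set(rb)):
        out.append(f"reaction {rid!r} only in first")
    for rid in sorted(set(rb) - set(ra)):
        out.append(f"reaction {rid!r} only in second")
    for rid in sorted(set(ra) & set(rb)):
        x, y = ra[rid], rb[rid]
        if x.reactants != y.reactants or x.products != y.products:
            out.append(f"reaction {rid!r}: stoichiometry differs")
        if set(x.modifiers) != set(y.modifiers):
            out.append(f"reaction {rid!r}: modifiers differ")
        if _law_signature(x.rate_law) != _law_signature(y.rate_law):
            out.append(f"reaction {rid!r}: rate law differs")

    ea = sorted(a.events, key=lambda e: (e.trigger_time, sorted(e.assignments)))
    eb = sorted(b.events, key=lambda e: (e.trigger_time, sorted(e.assignments)))
    if len(ea) != len(eb):
        out.append(f"event count {len(ea)} != {len(eb)}")
    else:
        for i, (x, y) in enumerate(zip(ea, eb)):
            if not math.isclose(x.trigger_time, y.trigger_time, rel_tol=rel_tol,
                                abs_tol=1e-9) or x.assignments != y.assignments:
                out.append(f"event[{i}] differs: {x} != {y}")
    return out


# ---------------------------------------------------------------------------
# bundled reference model
# ---------------------------------------------------------------------------

def reference_model_path():
    """Path of the bundled reference SBML file.

    The file is a synthetic stand-in generated by this package's own exporter
    (the published supplementary SBML is not redistributed here): the full
    immunotherapy model with passive immunisation at day 4, the scenario the
    published model file encodes. It pins the SBML serialisation and lets the
    import path be exercised against a file not produced in-process.
    """
    from importlib.resources import files
    return files("abtau").joinpath("data/reference_model_synthetic.xml")


def load_reference_model() -> ReactionNetwork:
    """Import the bundled reference model (see :func:`reference_model_path`)."""
    from importlib.resources import as_file
    with as_file(reference_model_path()) as p:
        return import_sbml(p)
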