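"""Reaction-network data model.

A :class:`ReactionNetwork` is a closed, well-mixed biochemical system: species
with integer initial molecule counts, global rate constants, reactions with
integer stoichiometry and a kinetic rate law, and time-triggered events that
reassign species counts mid-simulation (the mechanism used here to model a
bolus of anti-Abeta antibody).

All rate constants are in per-second units (s^-1 for first order,
molecule^-1 s^-1 for second order, molecule s^-1 for zeroth order); the
simulation clock is in seconds.
"""

from __future__ import annotations

import copy as _copy
import hashlib
import math
from dataclasses import dataclass, field, replace

__all__ = [
    "Species",
    "Parameter",
    "Saturation",
    "RateLaw",
    "Reaction",
    "TimedEvent",
    "ReactionNetwork",
    "Violation",
    "validate_network",
    "GLIA_POOL",
    "DAY",
]

#: seconds per day; "day T" always means T * DAY seconds of simulated time
DAY = 86_400.0

#: microglia states whose total is conserved by every reaction touching them
GLIA_POOL = ("GliaI", "GliaP1", "GliaP2", "GliaA", "AbP_GliaA")


@dataclass
class Species:
    id: str
    initial_amount: float = 0.0
    description: str = ""

    def __post_init__(self) -> None:
        if self.initial_amount < 0:
            raise ValueError(f"species {self.id!r}: negative initial amount")


@dataclass
class Parameter:
    """A global rate constant.

    ``provenance`` records where the value came from: ``published`` (printed in
    the source tables / measured turnover rates), ``calibrated`` (chosen to
    reproduce the documented time-course behaviour), ``scan-default`` (the
    alternative defaults used for sensitivity scans) or ``override`` (set by a
    scenario or by the user).
    """

    id: str
    value: float
    provenance: str = "calibrated"

    def __post_init__(self) -> None:
        if self.value < 0:
            raise ValueError(f"parameter {self.id!r}: negative value")


@dataclass(frozen=True)
class Saturation:
    """Saturating (Hill, coefficient 1) factor ``S / (S + half)``."""

    substrate: str
    half_param: str


@dataclass(frozen=True)
class RateLaw:
    """Kinetic rate law evaluated on molecule counts.

    ``mass_action``: rate = k * prod(counts of reactant_factors).
    ``saturating``:  rate = k * prod(factors) * S / (S + half); monotone
    non-decreasing and bounded in the saturating substrate S. Used for the
    plaque-growth law, where deposition of dimers rises linearly with plaque
    size before levelling off at a maximum rate.
    ``expression``: an interpreted expression tree (nested tuples) for laws
    read from SBML that match neither pattern; simulation falls back to a
    slower interpreted path rather than refusing the model.

    Expression nodes: ("param", id), ("species", id), ("num", v), ("time",)
    and (op, *args) with op in  +  -  *  /  pow.
    """

    kind: str  # "mass_action" | "saturating" | "expression"
    rate_constant: str = ""
    reactant_factors: tuple[str, ...] = ()
    saturation: Saturation | None = None
    expression: tuple | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("mass_action", "saturating", "expression"):
            raise ValueError(f"unknown rate-law kind {self.kind!r}")
        if self.kind == "saturating" and self.saturation is None:
            raise ValueError("saturating law requires a Saturation spec")
        if self.kind == "expression" and self.expression is None:
            raise ValueError("expression law requires an expression tree")
        if self.kind != "expression" and not self.rate_constant:
            raise ValueError("rate law requires a rate constant")

    def referenced_parameters(self) -> set[str]:
        refs: set[str] = set()
        if self.rate_constant:
            refs.add(self.rate_constant)
        if self.saturation is not None:
            refs.add(self.saturation.half_param)
        if self.expression is not None:
            refs |= _walk_expr(self.expression, "param")
        return refs

    def referenced_species(self) -> set[str]:
        refs = set(self.reactant_factors)
        if self.saturation is not None:
            refs.add(self.saturation.substrate)
        if self.expression is not None:
            refs |= _walk_expr(self.expression, "species")
        return refs


def _walk_expr(node: tuple, tag: str) -> set[str]:
    if not isinstance(node, tuple):
        return set()
    if node[0] == tag:
        return {node[1]}
    if node[0] in ("param", "species", "num", "time"):
        return set()
    out: set[str] = set()
    for child in node[1:]:
        out |= _walk_expr(child, tag)
    return out


@dataclass
class Reaction:
    id: str
    reactants: dict[str, int] = field(default_factory=dict)
    products: dict[str, int] = field(default_factory=dict)
    modifiers: tuple[str, ...] = ()
    rate_law: RateLaw | None = None

    def delta(self) -> dict[str, int]:
        """Net stoichiometric change per firing."""
        d: dict[str, int] = {}
        for s, n in self.products.items():
            d[s] = d.get(s, 0) + n
        for s, n in self.reactants.items():
            d[s] = d.get(s, 0) - n
        return {s: n for s, n in d.items() if n != 0}

    def referenced_species(self) -> set[str]:
        refs = set(self.reactants) | set(self.products) | set(self.modifiers)
        if self.rate_law is not None:
            refs |= self.rate_law.referenced_species()
        return refs


@dataclass
class TimedEvent:
    """Discrete assignment fired exactly once when time reaches trigger_time."""

    trigger_time: float
    assignments: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.trigger_time < 0:
            raise ValueError("event trigger time must be non-negative")


@dataclass
class ReactionNetwork:
    species: list[Species] = field(default_factory=list)
    parameters: list[Parameter] = field(default_factory=list)
    reactions: list[Reaction] = field(default_factory=list)
    events: list[TimedEvent] = field(default_factory=list)
    name: str = "network"

    # -- lookups ---------------------------------------------------------
    def species_ids(self) -> list[str]:
        return [s.id for s in self.species]

    def get_species(self, sid: str) -> Species:
        for s in self.species:
            if s.id == sid:
                return s
        raise KeyError(f"unknown species {sid!r}")

    def has_species(self, sid: str) -> bool:
        return any(s.id == sid for s in self.species)

    def get_parameter(self, pid: str) -> Parameter:
        for p in self.parameters:
            if p.id == pid:
                return p
        raise KeyError(f"unknown parameter {pid!r}")

    def has_parameter(self, pid: str) -> bool:
        return any(p.id == pid for p in self.parameters)

    def get_reaction(self, rid: str) -> Reaction:
        for r in self.reactions:
            if r.id == rid:
                return r
        raise KeyError(f"unknown reaction {rid!r}")

    def parameter_values(self) -> dict[str, float]:
        return {p.id: p.value for p in self.parameters}

    # -- non-destructive editing ----------------------------------------
    def copy(self) -> "ReactionNetwork":
        return _copy.deepcopy(self)

    def with_parameter(self, pid: str, value: float,
                       provenance: str = "override") -> "ReactionNetwork":
        """Copy of the network with one rate constant replaced."""
        net = self.copy()
        p = net.get_parameter(pid)
        p.value = value
        p.provenance = provenance
        return net

    def set_initial(self, sid: str, amount: float) -> None:
        self.get_species(sid).initial_amount = amount

    def initial_state(self) -> dict[str, float]:
        return {s.id: s.initial_amount for s in self.species}

    def content_hash(self) -> str:
        """Stable hash of the model structure (provenance-insensitive)."""
        parts: list[str] = [self.name]
        for s in sorted(self.species, key=lambda x: x.id):
            parts.append(f"S|{s.id}|{s.initial_amount!r}")
        for p in sorted(self.parameters, key=lambda x: x.id):
            parts.append(f"P|{p.id}|{p.value!r}")
        for r in sorted(self.reactions, key=lambda x: x.id):
            law = r.rate_law
            lawrepr = "" if law is None else (
                f"{law.kind}|{law.rate_constant}|{','.join(sorted(law.reactant_factors))}"
                + ("" if law.saturation is None
                   else f"|{law.saturation.substrate}/{law.saturation.half_param}")
            )
            parts.append(
                f"R|{r.id}|{sorted(r.reactants.items())}|{sorted(r.products.items())}"
                f"|{sorted(r.modifiers)}|{lawrepr}"
            )
        for e in sorted(self.events, key=lambda x: x.trigger_time):
            parts.append(f"E|{e.trigger_time!r}|{sorted(e.assignments.items())}")
        return hashlib.sha256("\n".join(parts).encode()).hexdigest()


@dataclass(frozen=True)
class Violation:
    kind: str
    element: str
    message: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"[{self.kind}] {self.element}: {self.message}"


def validate_network(net: ReactionNetwork) -> list[Violation]:
    """Check all structural invariants; violations are data, not exceptions.

    Checks: unique ids, non-negative integer initial amounts, positive integer
    stoichiometries, every referenced species/parameter declared, and exact
    conservation of the total microglial pool by every reaction touching it.
    """
    out: list[Violation] = []
    sids = [s.id for s in net.species]
    declared = set(sids)
    if len(sids) != len(declared):
        dupes = sorted({x for x in sids if sids.count(x) > 1})
        for d in dupes:
            out.append(Violation("duplicate-species", d, "species id declared twice"))
    pids = [p.id for p in net.parameters]
    declared_p = set(pids)
    if len(pids) != len(declared_p):
        for d in sorted({x for x in pids if pids.count(x) > 1}):
            out.append(Violation("duplicate-parameter", d, "parameter id declared twice"))

    for s in net.species:
        if s.initial_amount < 0:
            out.append(Violation("negative-initial", s.id, f"initial {s.initial_amount}"))
        if float(s.initial_amount) != float(int(s.initial_amount)):
            out.append(Violation("non-integer-initial", s.id, f"initial {s.initial_amount}"))

    rids = [r.id for r in net.reactions]
    if len(rids) != len(set(rids)):
        for d in sorted({x for x in rids if rids.count(x) > 1}):
            out.append(Violation("duplicate-reaction", d, "reaction id declared twice"))

    for r in net.reactions:
        for side_name, side in (("reactant", r.reactants), ("product", r.products)):
            for sid, n in side.items():
                if not (isinstance(n, int) and n > 0):
                    out.append(Violation("bad-stoichiometry", r.id,
                                         f"{side_name} {sid} has stoichiometry {n!r}"))
        missing = r.referenced_species() - declared
        for sid in sorted(missing):
            out.append(Violation("undeclared-species", r.id,
                                 f"references undeclared species {sid!r}"))
        if r.rate_law is not None:
            for pid in sorted(r.rate_law.referenced_parameters() - declared_p):
                out.append(Violation("undeclared-parameter", r.id,
                                     f"rate-law parameter {pid!r} not declared"))
        else:
            out.append(Violation("missing-rate-law", r.id, "reaction has no rate law"))
        # glia bookkeeping: microglia change state but are never created/destroyed
        d = r.delta()
        if any(s in d for s in GLIA_POOL):
            net_glia = sum(d.get(s, 0) for s in GLIA_POOL)
            if net_glia != 0:
                out.append(Violation("glia-conservation", r.id,
                                     f"net glia change {net_glia:+d}"))

    for i, e in enumerate(net.events):
        for sid, val in e.assignments.items():
            if sid not in declared:
                out.append(Violation("undeclared-species", f"event[{i}]",
                                     f"assigns undeclared species {sid!r}"))
            if val < 0 or not math.isfinite(val):
                out.append(Violation("bad-assignment", f"event[{i}]",
                                     f"{sid} := {val}"))
    return out
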