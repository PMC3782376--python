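"""Rate-law evaluation on molecule counts.

Both engines use the same rate expressions evaluated on raw molecule counts:
second-order mass action is k*X*Y with no combinatorial correction and no
volume scaling, and the deterministic engine works in count units so its
output is directly comparable with stochastic ensemble means.

``compile_network`` flattens a network into dense numpy arrays (stoichiometry,
rate-law opcodes, event table) consumed by the Gillespie inner loop and the
ODE right-hand side.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .network import ReactionNetwork, Reaction, validate_network

__all__ = [
    "SystemState",
    "propensity",
    "apply_reaction",
    "deterministic_rhs",
    "CompiledNetwork",
    "compile_network",
    "NotCompilableError",
    "eval_expression",
    "MASS_ACTION",
    "SATURATING",
]

MASS_ACTION = 0
SATURATING = 1

#: maximum number of multiplicative species factors in a single rate law
MAX_FACTORS = 3


@dataclass
class SystemState:
    """Time plus per-species counts (integers stochastically, reals in ODEs)."""

    time: float = 0.0
    counts: dict[str, float] = field(default_factory=dict)

    def copy(self) -> "SystemState":
        return SystemState(self.time, dict(self.counts))


class NotCompilableError(ValueError):
    """Raised when a network contains interpreted-expression rate laws that
    cannot be flattened for the fast engines."""


def eval_expression(node: tuple, counts: dict[str, float],
                    params: dict[str, float], time: float = 0.0) -> float:
    """Evaluate an interpreted rate-law expression tree."""
    op = node[0]
    if op == "num":
        return float(node[1])
    if op == "param":
        return params[node[1]]
    if op == "species":
        return counts[node[1]]
    if op == "time":
        return time
    args = [eval_expression(c, counts, params, time) for c in node[1:]]
    if op == "+":
        return sum(args)
    if op == "*":
        out = 1.0
        for a in args:
            out *= a
        return out
    if op == "-":
        return -args[0] if len(args) == 1 else args[0] - sum(args[1:])
    if op == "/":
        return args[0] / args[1]
    if op == "pow":
        return args[0] ** args[1]
    raise ValueError(f"unknown expression op {op!r}")


def _law_value(rxn: Reaction, counts: dict[str, float], params: dict[str, float],
               time: float = 0.0) -> float:
    law = rxn.rate_law
    if law is None:
        raise ValueError(f"reaction {rxn.id!r} has no rate law")
    if law.kind == "expression":
        try:
            return eval_expression(law.expression, counts, params, time)
        except KeyError as e:
            raise KeyError(f"reaction {rxn.id!r}: unknown symbol {e}")
    try:
        rate = params[law.rate_constant]
    except KeyError:
        raise KeyError(f"reaction {rxn.id!r}: unknown parameter {law.rate_constant!r}")
    for sid in law.reactant_factors:
        try:
            rate *= counts[sid]
        except KeyError:
            raise KeyError(f"reaction {rxn.id!r}: species {sid!r} missing from state")
    if law.kind == "saturating":
        sat = law.saturation
        try:
            s = counts[sat.substrate]
        except KeyError:
            raise KeyError(f"reaction {rxn.id!r}: species {sat.substrate!r} missing from state")
        half = params[sat.half_param]
        denom = s + half
        rate *= 0.0 if denom <= 0 else s / denom
    return rate


def propensity(rxn: Reaction, state: SystemState, params: dict[str, float]) -> float:
    """Instantaneous firing rate (s^-1) of ``rxn`` in ``state``.

    Zero whenever any consumed reactant has too few molecules for one firing,
    which guards every stochastic update against negative counts.
    """
    for sid in rxn.referenced_species():
        if sid not in state.counts:
            raise KeyError(f"reaction {rxn.id!r}: species {sid!r} missing from state")
    for sid, n in rxn.reactants.items():
        if state.counts[sid] < n:
            return 0.0
    return max(0.0, _law_value(rxn, state.counts, params))


def apply_reaction(rxn: Reaction, state: SystemState) -> SystemState:
    """State after one firing of ``rxn``; raises if a count would go negative."""
    new = state.copy()
    for sid, dn in rxn.delta().items():
        c = new.counts.get(sid, 0.0) + dn
        if c < 0:
            raise RuntimeError(
                f"reaction {rxn.id!r} drove {sid!r} negative; propensity guard bug")
        new.counts[sid] = c
    return new


def deterministic_rhs(net: ReactionNetwork, state: SystemState) -> dict[str, float]:
    """Net per-species rate vector (molecules/s) of the deterministic model.

    Identical rate expressions to :func:`propensity`, without the discrete
    reactant-count guard (counts are continuous).
    """
    params = net.parameter_values()
    rates: dict[str, float] = {s.id: 0.0 for s in net.species}
    for rxn in net.reactions:
        v = _law_value(rxn, state.counts, params)
        for sid, dn in rxn.delta().items():
            rates[sid] += dn * v
    return rates


@dataclass
class CompiledNetwork:
    """Dense-array form of a network for the numerical engines."""

    species: list[str]
    index: dict[str, int]
    x0: np.ndarray                 # (n_sp,) float64 initial amounts
    delta: np.ndarray              # (n_rxn, n_sp) float64 net stoichiometry
    react_stoich: np.ndarray       # (n_rxn, n_sp) float64 consumed stoichiometry
    kinds: np.ndarray              # (n_rxn,) int64 rate-law opcode
    kvals: np.ndarray              # (n_rxn,) float64 rate constants
    factors: np.ndarray            # (n_rxn, MAX_FACTORS) int64 species idx, -1 pad
    sat_sub: np.ndarray            # (n_rxn,) int64 substrate idx or -1
    sat_half: np.ndarray           # (n_rxn,) float64 half-saturation value
    event_times: np.ndarray        # (n_ev,) float64, ascending
    event_assign: np.ndarray       # (n_ev, n_sp) float64, NaN = untouched
    reaction_ids: list[str]

    @property
    def n_species(self) -> int:
        return len(self.species)

    @property
    def n_reactions(self) -> int:
        return len(self.reaction_ids)

    def rates(self, x: np.ndarray) -> np.ndarray:
        """Vector of rate-law values at continuous state ``x`` (no guards)."""
        v = self.kvals.copy()
        for j in range(MAX_FACTORS):
            idx = self.factors[:, j]
            mask = idx >= 0
            v[mask] *= x[idx[mask]]
        sat = self.kinds == SATURATING
        if sat.any():
            s = x[self.sat_sub[sat]]
            denom = s + self.sat_half[sat]
            frac = np.where(denom > 0, s / np.where(denom > 0, denom, 1.0), 0.0)
            v[sat] *= frac
        return v

    def rhs(self, t: float, x: np.ndarray) -> np.ndarray:
        return self.rates(np.maximum(x, 0.0)) @ self.delta


class InterpretedNetwork:
    """Duck-type stand-in for :class:`CompiledNetwork` (rhs/x0/events surface)
    that evaluates rate laws through the interpreter; used by the ODE engine
    when a network carries expression laws."""

    def __init__(self, net: ReactionNetwork):
        self.species = net.species_ids()
        self.index = {sid: i for i, sid in enumerate(self.species)}
        self.x0 = np.array([s.initial_amount for s in net.species], dtype=float)
        ev = sorted(net.events, key=lambda e: e.trigger_time)
        self.event_times = np.array([e.trigger_time for e in ev])
        self.event_assign = np.full((len(ev), len(self.species)), np.nan)
        for k, e in enumerate(ev):
            for sid, val in e.assignments.items():
                self.event_assign[k, self.index[sid]] = val
        self._net = net
        self._params = net.parameter_values()
        self._deltas = [r.delta() for r in net.reactions]

    @property
    def n_species(self) -> int:
        return len(self.species)

    def rhs(self, t: float, x: np.ndarray) -> np.ndarray:
        counts = {sid: max(float(v), 0.0) for sid, v in zip(self.species, x)}
        out = np.zeros_like(x, dtype=float)
        for rxn, delta in zip(self._net.reactions, self._deltas):
            v = _law_value(rxn, counts, self._params, t)
            for sid, dn in delta.items():
                out[self.index[sid]] += dn * v
        return out


def compile_network(net: ReactionNetwork, check: bool = True) -> CompiledNetwork:
    if check:
        violations = validate_network(net)
        if violations:
            msgs = "; ".join(str(v) for v in violations[:5])
            raise ValueError(f"network does not validate: {msgs}")
    species = [s.id for s in net.species]
    index = {sid: i for i, sid in enumerate(species)}
    n_sp = len(species)
    n_rxn = len(net.reactions)
    params = net.parameter_values()

    x0 = np.array([s.initial_amount for s in net.species], dtype=np.float64)
    delta = np.zeros((n_rxn, n_sp))
    react = np.zeros((n_rxn, n_sp))
    kinds = np.zeros(n_rxn, dtype=np.int64)
    kvals = np.zeros(n_rxn)
    factors = np.full((n_rxn, MAX_FACTORS), -1, dtype=np.int64)
    sat_sub = np.full(n_rxn, -1, dtype=np.int64)
    sat_half = np.zeros(n_rxn)

    for i, rxn in enumerate(net.reactions):
        law = rxn.rate_law
        if law.kind == "expression":
            raise NotCompilableError(
                f"reaction {rxn.id!r} uses an interpreted expression law; "
                "the engines fall back to the interpreted path")
        for sid, dn in rxn.delta().items():
            delta[i, index[sid]] = dn
        for sid, n in rxn.reactants.items():
            react[i, index[sid]] = n
        kvals[i] = params[law.rate_constant]
        if len(law.reactant_factors) > MAX_FACTORS:
            raise ValueError(f"reaction {rxn.id!r}: too many rate-law factors")
        for j, sid in enumerate(law.reactant_factors):
            factors[i, j] = index[sid]
        if law.kind == "saturating":
            kinds[i] = SATURATING
            sat_sub[i] = index[law.saturation.substrate]
            sat_half[i] = params[law.saturation.half_param]

    ev = sorted(net.events, key=lambda e: e.trigger_time)
    event_times = np.array([e.trigger_time for e in ev], dtype=np.float64)
    event_assign = np.full((len(ev), n_sp), np.nan)
    for k, e in enumerate(ev):
        for sid, val in e.assignments.items():
            event_assign[k, index[sid]] = val

    return CompiledNetwork(
        species=species, index=index, x0=x0, delta=delta, react_stoich=react,
        kinds=kinds, kvals=kvals, factors=factors, sat_sub=sat_sub,
        sat_half=sat_half, event_times=event_times, event_assign=event_assign,
        reaction_ids=[r.id for r in net.reactions],
    )
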