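"""Propensity evaluation, stoichiometric updates and the deterministic RHS."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from abtau.kinetics import (SystemState, apply_reaction, compile_network,
                            deterministic_rhs, eval_expression, propensity)
from abtau.network import (Parameter, RateLaw, Reaction, ReactionNetwork,
                           Species, GLIA_POOL)


def _state(net, **overrides):
    counts = net.initial_state()
    counts.update(overrides)
    return SystemState(0.0, counts)


def test_glia_activation_propensity_printed_value(full_model):
    """k_actglia1 * GliaI * AbP with the published constant."""
    rxn = full_model.get_reaction("GliaActivationStep1")
    state = _state(full_model, GliaI=100, AbP=10)
    assert propensity(rxn, state, full_model.parameter_values()) == pytest.approx(6.0e-4)


def test_antibody_binding_propensity_printed_value(full_model):
    rxn = full_model.get_reaction("AntiAbBindingToAbeta")
    state = _state(full_model, Abeta=1, antiAb=1)
    assert propensity(rxn, state, full_model.parameter_values()) == pytest.approx(1.0e-6)


def test_zero_reactant_gives_zero_propensity(full_model):
    rxn = full_model.get_reaction("AntiAbRemoval")
    state = _state(full_model, antiAb=0)
    assert propensity(rxn, state, full_model.parameter_values()) == 0.0


def test_missing_species_named_in_error(full_model):
    rxn = full_model.get_reaction("AntiAbRemoval")
    state = SystemState(0.0, {"Abeta": 1.0})
    with pytest.raises(KeyError, match="antiAb"):
        propensity(rxn, state, full_model.parameter_values())


@pytest.mark.parametrize("rid, before, after", [
    ("PlaqueClearanceByGlia", {"AbP_GliaA": 3, "GliaA": 0},
     {"AbP_GliaA": 2, "GliaA": 1}),
    ("ROSgenerationByPlaques", {"AbP": 10, "ROS": 0}, {"AbP": 10, "ROS": 1}),
    ("GliaInactivationStep3", {"GliaP1": 1, "GliaI": 0},
     {"GliaP1": 0, "GliaI": 1}),
])
def test_apply_reaction_stoichiometry(full_model, rid, before, after):
    state = _state(full_model, **before)
    new = apply_reaction(full_model.get_reaction(rid), state)
    for sid, expected in after.items():
        assert new.counts[sid] == expected


def test_apply_reaction_guards_against_negative(full_model):
    rxn = full_model.get_reaction("PlaqueClearanceByGlia")
    state = _state(full_model, AbP_GliaA=0)
    with pytest.raises(RuntimeError):
        apply_reaction(rxn, state)


def test_rhs_single_decay():
    """d(antiAb)/dt = -k * antiAb for an isolated antibody-removal network."""
    net = ReactionNetwork(
        species=[Species("antiAb", 50)],
        parameters=[Parameter("k_degAntiAb", 2.75e-6)],
        reactions=[Reaction("AntiAbRemoval", {"antiAb": 1}, {},
                            rate_law=RateLaw("mass_action", "k_degAntiAb",
                                             ("antiAb",)))])
    rates = deterministic_rhs(net, _state(net))
    assert rates["antiAb"] == pytest.approx(-50 * 2.75e-6)


def test_rhs_zero_glia_rate_without_plaques(full_model):
    """No plaques means no glial activation: the glial pool is inert."""
    counts = {s.id: 0.0 for s in full_model.species}
    counts["GliaI"] = 100.0
    rates = deterministic_rhs(full_model, SystemState(0.0, counts))
    for sid in GLIA_POOL:
        assert rates[sid] == 0.0


def test_rhs_mass_action_toy():
    net = ReactionNetwork(
        species=[Species("A", 4), Species("B", 0)],
        parameters=[Parameter("k", 0.5)],
        reactions=[Reaction("conv", {"A": 1}, {"B": 1},
                            rate_law=RateLaw("mass_action", "k", ("A",)))])
    rates = deterministic_rhs(net, _state(net))
    assert rates["A"] == pytest.approx(-2.0)
    assert rates["B"] == pytest.approx(+2.0)


def test_rhs_conserves_glia_everywhere(full_model):
    rng = np.random.default_rng(0)
    for _ in range(20):
        counts = {s.id: float(rng.integers(0, 100)) for s in full_model.species}
        rates = deterministic_rhs(full_model, SystemState(0.0, counts))
        assert sum(rates[s] for s in GLIA_POOL) == pytest.approx(0.0, abs=1e-12)


@settings(max_examples=50, deadline=None)
@given(st.dictionaries(
    st.sampled_from(["GliaI", "GliaP1", "GliaP2", "GliaA", "AbP_GliaA",
                     "AbP", "Abeta", "AbDim", "antiAb", "ROS"]),
    st.integers(min_value=0, max_value=1000)))
def test_propensities_nonnegative_and_guarded(counts):
    """For every state: propensity >= 0, and 0 whenever a consumed reactant
    is absent (so no update can go negative)."""
    net = build_cache()
    state_counts = {s.id: 0.0 for s in net.species}
    state_counts.update({k: float(v) for k, v in counts.items()})
    state = SystemState(0.0, state_counts)
    params = net.parameter_values()
    for rxn in net.reactions:
        a = propensity(rxn, state, params)
        assert a >= 0.0
        if any(state_counts[sid] < n for sid, n in rxn.reactants.items()):
            assert a == 0.0


_CACHE = {}


def build_cache():
    if "net" not in _CACHE:
        from abtau.model import build_model
        _CACHE["net"] = build_model()
    return _CACHE["net"]


def test_propensity_matches_compiled_rates(full_model):
    """The compiled rate vector equals per-reaction propensities whenever the
    guard is inactive (same expressions in both engines)."""
    cn = compile_network(full_model)
    rng = np.random.default_rng(1)
    params = full_model.parameter_values()
    for _ in range(10):
        # counts >= 2 keep every discrete reactant guard inactive
        x = rng.integers(2, 50, size=cn.n_species).astype(float)
        state = SystemState(0.0, dict(zip(cn.species, x)))
        rates = cn.rates(x)
        for i, rxn in enumerate(full_model.reactions):
            assert rates[i] == pytest.approx(
                propensity(rxn, state, params), rel=1e-12)


def test_expression_evaluation():
    expr = ("*", ("param", "k"), ("species", "A"),
            ("/", ("species", "S"), ("+", ("species", "S"), ("param", "h"))))
    val = eval_expression(expr, {"A": 4.0, "S": 50.0}, {"k": 0.5, "h": 50.0})
    assert val == pytest.approx(0.5 * 4 * 0.5)
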