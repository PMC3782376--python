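"""Exact stochastic engine: event handling, seeding, closed-form checks."""

import numpy as np
import pytest

from abtau.fixtures import make_fixture
from abtau.network import (DAY, Parameter, RateLaw, Reaction, ReactionNetwork,
                           Species, TimedEvent)
from abtau.ssa import replicate_seed, run_ensemble, simulate_ssa


def test_no_reactions_constant_trajectory():
    net = ReactionNetwork(species=[Species("A", 7)])
    tr = simulate_ssa(net, 12 * DAY, grid_step=DAY, seed=0)
    assert (tr.series("A") == 7).all()


def test_birth_death_stationary_mean():
    """Stationary law of the linear birth-death process is Poisson with mean
    k_birth/k_death = 10; the late-time ensemble mean must sit within 3
    standard errors of it."""
    net = make_fixture("birth_death")
    # relaxation time 1/k_death = 10 s; sample well past it
    ens = run_ensemble(net, horizon=200.0, grid_step=1.0, n_reps=300, base_seed=42)
    late = ens._expand("A")[:, 100:]          # (reps, times) past burn-in
    per_rep = late.mean(axis=1)
    se = per_rep.std(ddof=1) / np.sqrt(len(per_rep))
    assert abs(per_rep.mean() - 10.0) < 3 * se


def test_decay_matches_exponential():
    net = make_fixture("decay", scale=10)     # A0 = 500
    ens = run_ensemble(net, horizon=12 * DAY, grid_step=DAY, n_reps=200, base_seed=7)
    mean = ens.mean("A")
    sd = ens.sd("A")
    expected = 500 * np.exp(-2.75e-6 * ens.grid)
    se = np.maximum(sd / np.sqrt(ens.n_reps), 1e-9)
    assert (np.abs(mean - expected) <= 3 * se + 1e-9).mean() > 0.95


def test_event_sets_antibody_then_decays(full_model):
    net = full_model.copy()
    net.events.append(TimedEvent(4 * DAY, {"antiAb": 50}))
    tr = simulate_ssa(net, 12 * DAY, grid_step=0.05 * DAY, seed=3)
    y = tr.series("antiAb")
    before = y[tr.grid < 4 * DAY]
    at = y[np.isclose(tr.grid, 4 * DAY)]
    assert (before == 0).all()
    assert at[0] == 50                         # visible at first grid point >= trigger
    assert y[-1] < 50                          # antibody clears afterwards


def test_event_exactly_once():
    """An assignment fires once: later dynamics may move the species and the
    event must not re-trigger."""
    net = ReactionNetwork(
        species=[Species("A", 0)],
        parameters=[Parameter("k", 1.0)],
        reactions=[Reaction("deg", {"A": 1}, {},
                            rate_law=RateLaw("mass_action", "k", ("A",)))],
        events=[TimedEvent(10.0, {"A": 100})])
    tr = simulate_ssa(net, 100.0, grid_step=5.0, seed=0)
    y = tr.series("A")
    assert y[2] == 100                         # at t=10
    assert y[-1] < 100                         # decays, never reset again


def test_seeded_determinism(full_model):
    e1 = run_ensemble(full_model, 2 * DAY, grid_step=0.5 * DAY, n_reps=5, base_seed=11)
    e2 = run_ensemble(full_model, 2 * DAY, grid_step=0.5 * DAY, n_reps=5, base_seed=11)
    assert np.array_equal(e1.stack, e2.stack)
    assert e1.seeds == [replicate_seed(11, k) for k in range(5)]


def test_replicate_reproducible_in_isolation(full_model):
    ens = run_ensemble(full_model, 2 * DAY, grid_step=0.5 * DAY, n_reps=4, base_seed=5)
    solo = simulate_ssa(full_model, 2 * DAY, grid_step=0.5 * DAY,
                        seed=replicate_seed(5, 2))
    assert np.array_equal(ens.stack[2], solo.values)


def test_single_replicate_sd_zero(full_model):
    ens = run_ensemble(full_model, DAY, grid_step=0.5 * DAY, n_reps=1, base_seed=0)
    assert (ens.sd("Abeta") == 0).all()


def test_counts_nonnegative_integers(full_model):
    ens = run_ensemble(full_model, 3 * DAY, grid_step=0.25 * DAY, n_reps=5, base_seed=9)
    assert ens.stack.dtype == np.int64
    assert ens.stack.min() >= 0


def test_total_glia_conserved(full_model):
    ens = run_ensemble(full_model, 3 * DAY, grid_step=0.25 * DAY, n_reps=5, base_seed=13)
    assert (ens._expand("total_glia") == 100).all()


def test_glia_chain_conserves_population():
    net = make_fixture("glia_chain")
    ens = run_ensemble(net, horizon=50_000.0, grid_step=1000.0, n_reps=10, base_seed=1)
    total = sum(ens._expand(s) for s in ("G1", "G2", "G3", "G4"))
    assert (total == 100).all()


def test_non_integer_event_assignment_rejected(full_model):
    net = full_model.copy()
    net.events.append(TimedEvent(DAY, {"antiAb": 12.5}))
    with pytest.raises(ValueError, match="integer"):
        simulate_ssa(net, 2 * DAY, grid_step=DAY, seed=0)


def test_summarize_max_constant_and_monotone():
    net = ReactionNetwork(species=[Species("A", 5)])
    ens = run_ensemble(net, 10.0, grid_step=1.0, n_reps=2, base_seed=0)
    row = ens.summarize_max(["A"]).iloc[0]
    assert row.max_mean == 5 and row.t_max_s == 0.0

    birth = ReactionNetwork(
        species=[Species("N", 0)],
        parameters=[Parameter("k", 0.5)],
        reactions=[Reaction("b", {}, {"N": 1},
                            rate_law=RateLaw("mass_action", "k", ()))])
    ens = run_ensemble(birth, 100.0, grid_step=10.0, n_reps=3, base_seed=2)
    row = ens.summarize_max(["N"]).iloc[0]
    assert row.t_max_s == 100.0               # monotone increase peaks at horizon


def test_unknown_species_in_summary_errors(full_model):
    ens = run_ensemble(full_model, DAY, grid_step=DAY, n_reps=1, base_seed=0)
    with pytest.raises(KeyError):
        ens.summarize_max(["NotASpecies"])


def test_absorbing_state_fast_forwards():
    """All-zero propensities with no pending events is a valid absorbing
    state, not an error."""
    net = ReactionNetwork(
        species=[Species("A", 1)],
        parameters=[Parameter("k", 10.0)],
        reactions=[Reaction("deg", {"A": 1}, {},
                            rate_law=RateLaw("mass_action", "k", ("A",)))])
    tr = simulate_ssa(net, 1000.0, grid_step=100.0, seed=4)
    assert tr.series("A")[-1] == 0
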