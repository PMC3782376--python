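"""Small networks with closed-form behaviour, for engine validation.

Each fixture has a documented analytic solution the engines must reproduce:
ensemble means of linear networks match the ODE solution exactly (up to Monte
Carlo error), and the conserved-chain fixture mirrors the glial state cycle.
"""

from __future__ import annotations

from .network import Parameter, RateLaw, Reaction, ReactionNetwork, Species

__all__ = ["make_fixture", "FIXTURE_NAMES"]

FIXTURE_NAMES = ("decay", "birth_death", "dimerization", "glia_chain")


def make_fixture(name: str, scale: int = 1) -> ReactionNetwork:
    """Build a named toy network; ``scale`` multiplies copy numbers (and
    divides second-order constants) to probe convergence to the ODE limit.

    decay:        A -> 0 at k; A(t) = A0 exp(-kt). Defaults mirror antibody
                  clearance: A0=50, k=2.75e-6 s^-1 (half-life ~2.92 days).
    birth_death:  0 -> A at kb, A -> 0 at kd*A; stationary law is Poisson
                  with mean kb/kd = 10.
    dimerization: 2A <-> D; equilibrium kf*A^2 = kr*D (deterministic), total
                  mass A + 2D conserved.
    glia_chain:   4-state unidirectional cycle G1->G2->G3->G4->G1 conserving
                  the total population of 100*scale.
    """
    if name == "decay":
        return ReactionNetwork(
            species=[Species("A", 50 * scale)],
            parameters=[Parameter("k", 2.75e-6)],
            reactions=[Reaction("Decay", {"A": 1}, {},
                                rate_law=RateLaw("mass_action", "k", ("A",)))],
            name="decay")
    if name == "birth_death":
        return ReactionNetwork(
            species=[Species("A", 0)],
            parameters=[Parameter("k_birth", 1.0 * scale), Parameter("k_death", 0.1)],
            reactions=[
                Reaction("Birth", {}, {"A": 1},
                         rate_law=RateLaw("mass_action", "k_birth", ())),
                Reaction("Death", {"A": 1}, {},
                         rate_law=RateLaw("mass_action", "k_death", ("A",))),
            ],
            name="birth_death")
    if name == "dimerization":
        return ReactionNetwork(
            species=[Species("A", 100 * scale), Species("D", 0)],
            parameters=[Parameter("kf", 1.0e-3 / scale), Parameter("kr", 1.0e-2)],
            reactions=[
                Reaction("Dimerise", {"A": 2}, {"D": 1},
                         rate_law=RateLaw("mass_action", "kf", ("A", "A"))),
                Reaction("Dissociate", {"D": 1}, {"A": 2},
                         rate_law=RateLaw("mass_action", "kr", ("D",))),
            ],
            name="dimerization")
    if name == "glia_chain":
        ids = ["G1", "G2", "G3", "G4"]
        species = [Species(ids[0], 100 * scale)] + [Species(i, 0) for i in ids[1:]]
        reactions = []
        for a, b in zip(ids, ids[1:] + ids[:1]):
            reactions.append(Reaction(
                f"Step_{a}_{b}", {a: 1}, {b: 1},
                rate_law=RateLaw("mass_action", "k_step", (a,))))
        return ReactionNetwork(
            species=species, parameters=[Parameter("k_step", 1.0e-4)],
            reactions=reactions, name="glia_chain")
    raise ValueError(f"unknown fixture {name!r}; choose from {FIXTURE_NAMES}")
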