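"""Intervention scenarios as parameter/event overlays on the full model.

Five intervention shapes are modelled, all delivered through the antibody
species ``antiAb``:

* ``none``       — no antibody source; antiAb stays at zero;
* ``passive``    — a bolus: a timed event sets antiAb to the dose at each
                   listed day (one event per time; several times give repeated
                   immunisation);
* ``active``     — vaccination: a zeroth-order antibody production reaction is
                   added, so antibody rises toward the production/clearance
                   balance and stays elevated (no dosing events);
* ``prevention`` — antibody present from the start: the initial amount of
                   antiAb is the dose and no events are added.

"Day T" means the trigger fires at exactly T * 86,400 s of simulated time.
Scenario realisation is non-destructive: the base network is never mutated.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import yaml

from .network import DAY, Parameter, RateLaw, Reaction, ReactionNetwork, TimedEvent
from .model import AD_DEG_RATE
from .ode import simulate_ode
from .ssa import DEFAULT_GRID_STEP, run_ensemble

__all__ = ["ScenarioSpec", "realize_scenario", "run_scenario_suite",
           "standard_scenarios", "REPORTED_SPECIES", "K_SYN_ANTIAB"]

#: the fixed set of reported outputs (soluble Abeta = monomers + dimers;
#: the active GSK3beta pool is the GSK3beta-p53 complex)
REPORTED_SPECIES = ("soluble_Abeta", "AbP", "Tau_P2", "NFT", "GliaA", "ROS",
                    "Gsk3b_p53")

#: zeroth-order antibody production rate for active immunisation
#: (molecules/s); balances first-order clearance at an antibody level equal to
#: the standard passive dose: k_syn / k_degAntiAb = 50
K_SYN_ANTIAB = 50 * 2.75e-6

_KINDS = ("none", "passive", "repeated", "active", "prevention")


@dataclass
class ScenarioSpec:
    """One in-silico experiment: intervention kind, timing, dose, variant."""

    kind: str = "none"
    times_days: list[float] = field(default_factory=list)   # passive dosing days
    dose: int = 50
    k_degAbeta: float = AD_DEG_RATE
    horizon_days: float = 12.0
    overrides: dict[str, float] = field(default_factory=dict)
    name: str | None = None

    def __post_init__(self) -> None:
        if self.kind == "repeated":
            # alias: repeated passive dosing
            self.kind = "passive"
            if not self.times_days:
                self.times_days = [0.0, 7.0]
        if self.kind not in _KINDS:
            raise ValueError(f"unknown scenario kind {self.kind!r}; "
                             f"choose from {_KINDS}")
        if self.kind == "passive" and not self.times_days:
            self.times_days = [4.0]
        for t in self.times_days:
            if not 0 <= t <= self.horizon_days:
                raise ValueError(f"dosing time day {t} outside [0, {self.horizon_days}]")

    @property
    def label(self) -> str:
        if self.name:
            return self.name
        if self.kind == "passive":
            days = "+".join(f"d{t:g}" for t in self.times_days)
            return f"passive@{days}"
        return self.kind

    @property
    def horizon(self) -> float:
        return self.horizon_days * DAY

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ScenarioSpec":
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "ScenarioSpec":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


def realize_scenario(base: ReactionNetwork, spec: ScenarioSpec) -> ReactionNetwork:
    """Network implementing ``spec``; ``base`` is left untouched."""
    net = base.copy()
    net.events = [e for e in net.events]  # scenario events replace dosing only
    if not net.has_species("antiAb"):
        raise ValueError("base network lacks the antibody species 'antiAb'")

    par = net.get_parameter("k_degAbeta")
    if par.value != spec.k_degAbeta:
        par.value = spec.k_degAbeta
        par.provenance = "override"

    if spec.kind == "none":
        net.set_initial("antiAb", 0)
    elif spec.kind == "passive":
        net.set_initial("antiAb", 0)
        for t in sorted(spec.times_days):
            net.events.append(TimedEvent(t * DAY, {"antiAb": float(spec.dose)}))
    elif spec.kind == "prevention":
        net.set_initial("antiAb", spec.dose)
    elif spec.kind == "active":
        net.set_initial("antiAb", 0)
        if not net.has_parameter("k_synAntiAb"):
            net.parameters.append(Parameter("k_synAntiAb", K_SYN_ANTIAB, "calibrated"))
        net.reactions.append(Reaction(
            id="AntiAbProduction", reactants={}, products={"antiAb": 1},
            rate_law=RateLaw("mass_action", "k_synAntiAb", ())))

    for pid, val in spec.overrides.items():
        p = net.get_parameter(pid)
        p.value = val
        p.provenance = "override"
    net.name = f"{base.name}[{spec.label}]"
    return net


def standard_scenarios(k_degAbeta: float = AD_DEG_RATE) -> list[ScenarioSpec]:
    """The six standard intervention panels: passive dosing at day 0, 4 or 8,
    repeated dosing at days 0 and 7, active immunisation, and no treatment."""
    return [
        ScenarioSpec("passive", [0.0], k_degAbeta=k_degAbeta),
        ScenarioSpec("passive", [4.0], k_degAbeta=k_degAbeta),
        ScenarioSpec("passive", [8.0], k_degAbeta=k_degAbeta),
        ScenarioSpec("passive", [0.0, 7.0], k_degAbeta=k_degAbeta, name="repeated@d0+d7"),
        ScenarioSpec("active", k_degAbeta=k_degAbeta),
        ScenarioSpec("none", k_degAbeta=k_degAbeta),
    ]


def run_scenario_suite(base: ReactionNetwork, specs: list[ScenarioSpec],
                       engine: str = "ssa", n_reps: int = 100,
                       base_seed: int = 0, grid_step: float = DEFAULT_GRID_STEP):
    """Run every scenario with the selected engine.

    Returns ``{label: TrajectoryEnsemble}`` for the stochastic engine and
    ``{label: Trajectory}`` for the deterministic one. Reproducible given
    ``base_seed``; each scenario uses an independent seed block.
    """
    if engine not in ("ssa", "ode"):
        raise ValueError(f"unknown engine {engine!r}")
    out = {}
    for i, spec in enumerate(specs):
        net = realize_scenario(base, spec)
        if engine == "ode":
            out[spec.label] = simulate_ode(net, spec.horizon, grid_step)
        else:
            out[spec.label] = run_ensemble(net, spec.horizon, grid_step,
                                           n_reps=n_reps,
                                           base_seed=base_seed + 10_000 * i)
    return out
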