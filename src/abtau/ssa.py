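"""Exact stochastic simulation (Gillespie direct method) with timed events.

The jump process is simulated exactly: at each step the total propensity sets
an exponential waiting time and the next reaction is chosen proportionally to
its propensity. A time-triggered event truncates the waiting time at the
trigger (propensities are unchanged up to it, so by memorylessness this is
exact), applies its assignments atomically, and simulation resumes with
recomputed propensities. Recording on the output grid never perturbs the
process itself.

Replicate ``k`` of an ensemble uses seed ``(base_seed + k) mod 2**31``, so any
single replicate can be reproduced in isolation.
"""

from __future__ import annotations

import numpy as np
from numba import njit

from .kinetics import (CompiledNetwork, NotCompilableError, SystemState,
                       compile_network, propensity)
from .network import DAY, ReactionNetwork
from .trajectory import Trajectory, TrajectoryEnsemble, make_grid

__all__ = ["simulate_ssa", "run_ensemble", "replicate_seed", "DEFAULT_GRID_STEP"]

#: default recording step: 0.05 day (output resolution only; the process is exact)
DEFAULT_GRID_STEP = 0.05 * DAY


def replicate_seed(base_seed: int, k: int) -> int:
    """Counter-based seed derivation for replicate ``k``."""
    return int((int(base_seed) + int(k)) % 2**31)


@njit(cache=True)
def _ssa_core(x0, grid, delta, react, kinds, kvals, factors, sat_sub, sat_half,
              ev_times, ev_assign, seed):  # pragma: no cover - exercised via wrapper
    np.random.seed(seed)
    n_grid = grid.shape[0]
    n_rxn = delta.shape[0]
    n_sp = delta.shape[1]
    n_fac = factors.shape[1]
    horizon = grid[n_grid - 1]

    x = x0.copy()
    out = np.zeros((n_grid, n_sp), dtype=np.int64)
    t = 0.0
    gi = 0
    ev_i = 0
    n_ev = ev_times.shape[0]
    a = np.zeros(n_rxn)

    while True:
        # propensities with the negative-count guard
        a0 = 0.0
        for i in range(n_rxn):
            ok = True
            for s in range(n_sp):
                if react[i, s] > 0 and x[s] < react[i, s]:
                    ok = False
                    break
            if not ok:
                a[i] = 0.0
                continue
            v = kvals[i]
            for j in range(n_fac):
                f = factors[i, j]
                if f >= 0:
                    v *= x[f]
            if kinds[i] == 1:  # saturating
                s_ = x[sat_sub[i]]
                denom = s_ + sat_half[i]
                v = v * (s_ / denom) if denom > 0 else 0.0
            if v < 0.0:
                v = 0.0
            a[i] = v
            a0 += v

        next_ev = ev_times[ev_i] if ev_i < n_ev else np.inf
        boundary = next_ev if next_ev < horizon else horizon

        if a0 <= 0.0:
            t_next = np.inf
        else:
            t_next = t + np.random.exponential(1.0 / a0)

        if t_next >= boundary:
            # no jump before the boundary: flush grid, then event or finish
            while gi < n_grid and grid[gi] < boundary:
                for s in range(n_sp):
                    out[gi, s] = x[s]
                gi += 1
            if next_ev <= horizon:
                t = next_ev
                for s in range(n_sp):
                    if not np.isnan(ev_assign[ev_i, s]):
                        x[s] = np.int64(round(ev_assign[ev_i, s]))
                ev_i += 1
                continue
            # absorbing (or simply done): fast-forward to the horizon
            while gi < n_grid:
                for s in range(n_sp):
                    out[gi, s] = x[s]
                gi += 1
            return out

        # jump strictly before boundary
        while gi < n_grid and grid[gi] < t_next:
            for s in range(n_sp):
                out[gi, s] = x[s]
            gi += 1
        t = t_next
        u = np.random.random() * a0
        c = 0.0
        ri = n_rxn - 1
        for i in range(n_rxn):
            c += a[i]
            if u < c:
                ri = i
                break
        for s in range(n_sp):
            x[s] += np.int64(delta[ri, s])


def _check_integer(cn: CompiledNetwork) -> None:
    if not np.allclose(cn.x0, np.round(cn.x0)):
        raise ValueError("stochastic mode requires integer initial amounts")
    assign = cn.event_assign
    finite = ~np.isnan(assign)
    if finite.any() and not np.allclose(assign[finite], np.round(assign[finite])):
        raise ValueError("stochastic mode requires integer event assignments")


def _ssa_interpreted(net: ReactionNetwork, grid: np.ndarray, seed: int) -> np.ndarray:
    """Pure-python direct method for networks with interpreted rate laws.

    Slow; exists so imported models whose kinetics match no compiled pattern
    still simulate exactly.
    """
    rng = np.random.default_rng(seed)
    species = net.species_ids()
    params = net.parameter_values()
    state = SystemState(0.0, {s.id: float(round(s.initial_amount)) for s in net.species})
    horizon = grid[-1]
    events = sorted(net.events, key=lambda e: e.trigger_time)
    out = np.zeros((len(grid), len(species)), dtype=np.int64)
    gi, ev_i, t = 0, 0, 0.0
    deltas = [r.delta() for r in net.reactions]
    while True:
        props = np.array([propensity(r, state, params) for r in net.reactions])
        a0 = props.sum()
        next_ev = events[ev_i].trigger_time if ev_i < len(events) else np.inf
        boundary = min(next_ev, horizon)
        t_next = t + rng.exponential(1.0 / a0) if a0 > 0 else np.inf
        if t_next >= boundary:
            while gi < len(grid) and grid[gi] < boundary:
                out[gi] = [state.counts[s] for s in species]
                gi += 1
            if next_ev <= horizon:
                t = next_ev
                for sid, val in events[ev_i].assignments.items():
                    state.counts[sid] = float(round(val))
                ev_i += 1
                continue
            while gi < len(grid):
                out[gi] = [state.counts[s] for s in species]
                gi += 1
            return out
        while gi < len(grid) and grid[gi] < t_next:
            out[gi] = [state.counts[s] for s in species]
            gi += 1
        t = t_next
        ri = int(np.searchsorted(np.cumsum(props), rng.random() * a0))
        for sid, dn in deltas[ri].items():
            state.counts[sid] += dn


def simulate_ssa(net: ReactionNetwork | CompiledNetwork, horizon: float,
                 grid_step: float = DEFAULT_GRID_STEP, seed: int = 0) -> Trajectory:
    """One exact stochastic trajectory sampled on a fixed grid."""
    if isinstance(net, ReactionNetwork):
        try:
            cn = compile_network(net)
        except NotCompilableError:
            grid = make_grid(horizon, grid_step)
            values = _ssa_interpreted(net, grid, int(seed) % 2**31)
            return Trajectory(grid=grid, species=net.species_ids(),
                              values=values, seed=int(seed))
    else:
        cn = net
    _check_integer(cn)
    grid = make_grid(horizon, grid_step)
    values = _ssa_core(
        cn.x0.astype(np.int64), grid, cn.delta, cn.react_stoich, cn.kinds,
        cn.kvals, cn.factors, cn.sat_sub, cn.sat_half,
        cn.event_times, cn.event_assign, int(seed) % 2**31)
    return Trajectory(grid=grid, species=list(cn.species), values=values, seed=int(seed))


def run_ensemble(net: ReactionNetwork | CompiledNetwork, horizon: float,
                 grid_step: float = DEFAULT_GRID_STEP, n_reps: int = 100,
                 base_seed: int = 0) -> TrajectoryEnsemble:
    """``n_reps`` independent trajectories; bit-for-bit reproducible given
    the network and ``base_seed``."""
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    seeds = [replicate_seed(base_seed, k) for k in range(n_reps)]
    grid = make_grid(horizon, grid_step)
    if isinstance(net, ReactionNetwork):
        try:
            cn = compile_network(net)
        except NotCompilableError:
            stack = np.stack([_ssa_interpreted(net, grid, s) for s in seeds])
            return TrajectoryEnsemble(grid=grid, species=net.species_ids(),
                                      stack=stack, seeds=seeds)
    else:
        cn = net
    _check_integer(cn)
    stack = np.zeros((n_reps, grid.shape[0], cn.n_species), dtype=np.int64)
    x0 = cn.x0.astype(np.int64)
    for k, seed in enumerate(seeds):
        stack[k] = _ssa_core(
            x0, grid, cn.delta, cn.react_stoich, cn.kinds, cn.kvals,
            cn.factors, cn.sat_sub, cn.sat_half,
            cn.event_times, cn.event_assign, seed)
    return TrajectoryEnsemble(grid=grid, species=list(cn.species), stack=stack, seeds=seeds)
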