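"""One-at-a-time half/double parameter scans with effect ranking.

Each rate constant is varied in turn to 0.5x and 2x its default while all
others stay at their defaults; the deterministic engine integrates the day-4
passive-immunisation scenario over 12 days, and the maximum level of each
reported output over the whole horizon is compared with the unperturbed
maximum. Outputs are classified up/down/no-effect per direction, parameters
are ranked by the largest achievable percentage reduction of a primary output
(plaques or tangles), and the ranking is compared with the ranking for a
secondary output (soluble Abeta or phospho-tau) by Pearson correlation of the
paired ranks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .model import apply_scan_defaults, build_model
from .network import DAY, ReactionNetwork
from .ode import simulate_ode
from .reference import OUTPUTS
from .scenarios import ScenarioSpec, realize_scenario

__all__ = ["scan_model", "scan_all", "rank_by_effect", "rank_correlation",
           "count_directions", "ScanSettings"]

#: outputs with |relative change in max| below this are classed "no effect"
SIGNIFICANCE_THRESHOLD = 0.005


@dataclass
class ScanSettings:
    factors: tuple[float, ...] = (0.5, 2.0)
    outputs: tuple[str, ...] = OUTPUTS
    horizon: float = 12 * DAY
    output_step: float = 0.1 * DAY
    rtol: float = 1e-8
    atol: float = 1e-10
    threshold: float = SIGNIFICANCE_THRESHOLD


def scan_model() -> ReactionNetwork:
    """The network all scans run on: full model, scan-default ROS-generation
    rates, day-4 passive immunisation (the scenario where the deterministic
    and stochastic engines agree best)."""
    net = apply_scan_defaults(build_model())
    return realize_scenario(net, ScenarioSpec("passive", [4.0]))


def _maxima(net: ReactionNetwork, settings: ScanSettings) -> dict[str, float]:
    tr = simulate_ode(net, settings.horizon, settings.output_step,
                      rtol=settings.rtol, atol=settings.atol)
    return {name: tr.max_of(name)[0] for name in settings.outputs}


def _scannable_parameters(net: ReactionNetwork) -> list[str]:
    """Parameters referenced by at least one rate law (incl. half-saturation)."""
    used: set[str] = set()
    for r in net.reactions:
        if r.rate_law is not None:
            used.add(r.rate_law.rate_constant)
            if r.rate_law.saturation is not None:
                used.add(r.rate_law.saturation.half_param)
    return [p.id for p in net.parameters if p.id in used]


def scan_all(net: ReactionNetwork | None = None,
             settings: ScanSettings | None = None,
             parameters: list[str] | None = None) -> pd.DataFrame:
    """Run the full scan; tidy result, one row per (parameter, factor, output).

    Columns: parameter, factor, output, max_level, baseline_max, pct_decrease
    (100*(baseline-perturbed)/baseline; negative = increase), effect
    (+1 increase / -1 decrease / 0 below threshold), failed (integrator
    failure on that perturbed model; scan continues).
    """
    if net is None:
        net = scan_model()
    settings = settings or ScanSettings()
    if parameters is None:
        parameters = _scannable_parameters(net)
    baseline = _maxima(net, settings)

    rows = []
    for pid in parameters:
        default = net.get_parameter(pid).value
        for factor in settings.factors:
            failed = False
            try:
                maxima = (baseline if factor == 1.0 else
                          _maxima(net.with_parameter(pid, default * factor), settings))
            except RuntimeError:
                maxima, failed = {name: np.nan for name in settings.outputs}, True
            for name in settings.outputs:
                base, mx = baseline[name], maxima[name]
                if failed or base <= 0:
                    pct = np.nan if failed else 0.0
                    rel = 0.0
                else:
                    pct = 100.0 * (base - mx) / base
                    rel = (mx - base) / base
                if failed or abs(rel) < settings.threshold:
                    eff = 0
                else:
                    eff = 1 if rel > 0 else -1
                rows.append({
                    "parameter": pid, "factor": factor, "output": name,
                    "max_level": mx, "baseline_max": base,
                    "pct_decrease": pct, "effect": eff, "failed": failed,
                })
    return pd.DataFrame(rows)


def rank_by_effect(results: pd.DataFrame, primary: str,
                   secondary: str) -> pd.DataFrame:
    """Rank parameters by largest achievable % reduction of ``primary``.

    For each parameter the direction (halving -> "down", doubling -> "up")
    giving the larger reduction of the primary output is kept; parameters with
    no significant primary effect are dropped. The secondary output's %
    reduction in the same direction is ranked over the same parameter set;
    parameters with no secondary effect share the lowest rank (n).
    """
    rows = []
    for pid, grp in results.groupby("parameter", sort=False):
        prim = grp[(grp.output == primary) & (~grp.failed)]
        if prim.empty:
            continue
        best = prim.loc[prim.pct_decrease.idxmax()]
        sig = prim[prim.effect != 0]
        if sig.empty or best.pct_decrease <= 0:
            continue
        direction = "down" if best.factor < 1 else "up"
        sec = grp[(grp.output == secondary) & (grp.factor == best.factor)]
        sec_pct = float(sec.pct_decrease.iloc[0]) if len(sec) else 0.0
        sec_sig = bool(len(sec) and sec.effect.iloc[0] != 0)
        rows.append({
            "parameter": pid, "direction": direction,
            f"pct_decrease_{primary}": float(best.pct_decrease),
            f"pct_decrease_{secondary}": sec_pct,
            "secondary_significant": sec_sig,
        })
    table = pd.DataFrame(rows)
    if table.empty:
        return table
    table = table.sort_values(f"pct_decrease_{primary}",
                              ascending=False, ignore_index=True)
    table["rank"] = np.arange(1, len(table) + 1)
    n = len(table)
    sec_col = f"pct_decrease_{secondary}"
    sec_rank = np.full(n, n, dtype=int)
    sig_mask = table["secondary_significant"].to_numpy()
    order = np.argsort(-table.loc[sig_mask, sec_col].to_numpy(), kind="stable")
    sec_rank_vals = np.empty(order.size, dtype=int)
    sec_rank_vals[order] = np.arange(1, order.size + 1)
    sec_rank[sig_mask] = sec_rank_vals
    table["secondary_rank"] = sec_rank
    cols = ["rank", "parameter", "direction", f"pct_decrease_{primary}",
            "secondary_rank", sec_col, "secondary_significant"]
    return table[cols]


def rank_correlation(primary_ranks, secondary_ranks) -> tuple[float, float]:
    """Pearson product-moment correlation and two-sided p-value between two
    paired rank columns (ranks treated as plain paired values)."""
    a = np.asarray(primary_ranks, dtype=float)
    b = np.asarray(secondary_ranks, dtype=float)
    if a.size != b.size or a.size < 3:
        raise ValueError("need at least 3 paired ranks")
    if np.all(a == a[0]) or np.all(b == b[0]):
        raise ValueError("correlation undefined: a rank column is constant")
    r, p = stats.pearsonr(a, b)
    return float(r), float(p)


def count_directions(table: pd.DataFrame) -> tuple[int, int]:
    """(number of parameters whose output-reducing direction is a doubling,
    number for which it is a halving)."""
    if table.empty or "direction" not in table:
        return (0, 0)
    up = int((table["direction"] == "up").sum())
    down = int((table["direction"] == "down").sum())
    return up, down
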