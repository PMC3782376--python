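"""Fixed-grid trajectories and replicate ensembles.

Stochastic trajectories are right-continuous piecewise-constant samples of the
jump process on a fixed recording grid; ensembles summarise replicates by
per-grid-point mean and standard deviation, the form in which the model's
time courses are reported (mean curve plus a one-standard-deviation band).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .network import GLIA_POOL, DAY

__all__ = ["Trajectory", "TrajectoryEnsemble", "make_grid", "DERIVED_SERIES"]

#: reported quantities that are sums of model species. The soluble Abeta pool
#: is monomers plus dimers; antibody-bound complexes are excluded from it.
DERIVED_SERIES: dict[str, tuple[str, ...]] = {
    "soluble_Abeta": ("Abeta", "AbDim"),
    "total_glia": GLIA_POOL,
}


def make_grid(horizon: float, step: float) -> np.ndarray:
    """Uniform recording grid 0..horizon inclusive (horizon always included)."""
    if horizon <= 0 or step <= 0:
        raise ValueError("horizon and step must be positive")
    n = int(round(horizon / step))
    grid = np.linspace(0.0, n * step, n + 1)
    if not np.isclose(grid[-1], horizon):
        grid = np.append(grid[grid < horizon], horizon)
    return grid


@dataclass
class Trajectory:
    grid: np.ndarray
    species: list[str]
    values: np.ndarray          # (n_grid, n_species)
    seed: int | None = None

    def _col(self, name: str) -> np.ndarray:
        if name in self.species:
            return self.values[:, self.species.index(name)].astype(float)
        if name in DERIVED_SERIES:
            cols = [s for s in DERIVED_SERIES[name] if s in self.species]
            if not cols:
                raise KeyError(f"derived series {name!r}: no member species present")
            return sum(self._col(c) for c in cols)
        raise KeyError(f"unknown species or derived series {name!r}")

    def series(self, name: str) -> np.ndarray:
        """Time series for a species id or a derived series name."""
        return self._col(name)

    def max_of(self, name: str) -> tuple[float, float]:
        """(max over the grid, time of the max)."""
        y = self.series(name)
        i = int(np.argmax(y))
        return float(y[i]), float(self.grid[i])

    def final(self, name: str) -> float:
        return float(self.series(name)[-1])

    def to_frame(self, species: list[str] | None = None) -> pd.DataFrame:
        """Tidy long format: time_s, time_d, species, value."""
        names = species if species is not None else list(self.species)
        frames = []
        for name in names:
            frames.append(pd.DataFrame({
                "time_s": self.grid,
                "time_d": self.grid / DAY,
                "species": name,
                "value": self.series(name),
            }))
        return pd.concat(frames, ignore_index=True)


@dataclass
class TrajectoryEnsemble:
    grid: np.ndarray
    species: list[str]
    stack: np.ndarray           # (n_reps, n_grid, n_species)
    seeds: list[int] = field(default_factory=list)

    @property
    def n_reps(self) -> int:
        return self.stack.shape[0]

    def replicate(self, k: int) -> Trajectory:
        seed = self.seeds[k] if k < len(self.seeds) else None
        return Trajectory(self.grid, self.species, self.stack[k], seed=seed)

    def _expand(self, name: str) -> np.ndarray:
        """(n_reps, n_grid) array for a species or derived series."""
        if name in self.species:
            return self.stack[:, :, self.species.index(name)].astype(float)
        if name in DERIVED_SERIES:
            cols = [s for s in DERIVED_SERIES[name] if s in self.species]
            if not cols:
                raise KeyError(f"derived series {name!r}: no member species present")
            return sum(self._expand(c) for c in cols)
        raise KeyError(f"unknown species or derived series {name!r}")

    def mean(self, name: str) -> np.ndarray:
        return self._expand(name).mean(axis=0)

    def sd(self, name: str) -> np.ndarray:
        y = self._expand(name)
        if y.shape[0] < 2:
            return np.zeros(y.shape[1])
        return y.std(axis=0, ddof=1)

    def mean_trajectory(self) -> Trajectory:
        return Trajectory(self.grid, self.species, self.stack.mean(axis=0).astype(float))

    def summarize_max(self, names: list[str]) -> pd.DataFrame:
        """Max over the grid of the ensemble mean curve, its time, and the
        per-replicate maxima (mean and SD) for dispersion."""
        rows = []
        for name in names:
            m = self.mean(name)
            i = int(np.argmax(m))
            rep_max = self._expand(name).max(axis=1)
            rows.append({
                "species": name,
                "max_mean": float(m[i]),
                "t_max_s": float(self.grid[i]),
                "t_max_d": float(self.grid[i] / DAY),
                "rep_max_mean": float(rep_max.mean()),
                "rep_max_sd": float(rep_max.std(ddof=1)) if self.n_reps > 1 else 0.0,
            })
        return pd.DataFrame(rows)

    def to_frame(self, species: list[str] | None = None) -> pd.DataFrame:
        """Tidy summary: time_s, time_d, species, mean, sd."""
        names = species if species is not None else list(self.species)
        frames = []
        for name in names:
            frames.append(pd.DataFrame({
                "time_s": self.grid,
                "time_d": self.grid / DAY,
                "species": name,
                "mean": self.mean(name),
                "sd": self.sd(name),
            }))
        return pd.concat(frames, ignore_index=True)
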