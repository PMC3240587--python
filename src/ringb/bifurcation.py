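"""One-parameter steady-state scans, hysteresis protocols and regime maps.

Branches are tracked by warm-started root refinement (continuation) combined
with seeded multi-start enumeration at every grid point; saddle-node (fold)
locations are refined by bisection on the steady-state count.  Pseudo-
arclength continuation is deliberately avoided: at this system size the
count-bisection approach is robust and directly checkable against the
quasi-static hysteresis protocol.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .model import ModelConfig, ParameterSet
from .steady import (SteadyState, find_steady_states, classify_regime,
                     _refine, _reduce, _expand)

__all__ = ["BifurcationBranch", "RegimeMap", "scan_1d", "hysteresis_sweep",
           "regime_map"]

#: a jump in Zub larger than this between consecutive quasi-static steps
#: counts as a branch switch.
JUMP_THRESHOLD = 0.08


def _states_at(params: ParameterSet, config: ModelConfig, param_name: str,
               value: float, warm, n_starts: int, seed: int):
    p = params.replace(**{param_name: value})
    return p, find_steady_states(p, config, n_starts=n_starts, seed=seed,
                                 warm_starts=warm)


@dataclass
class BifurcationBranch:
    """Steady states along a scanned parameter, with fold locations."""

    param_name: str
    grid: np.ndarray
    states: list                   # list (per grid point) of SteadyState
    folds: list                    # parameter values of saddle-node points
    config: ModelConfig

    def counts(self) -> np.ndarray:
        return np.array([len(s) for s in self.states])

    def as_frame(self):
        import pandas as pd
        rows = []
        species = self.config.species
        for g, sts in zip(self.grid, self.states):
            for s in sts:
                rows.append({self.param_name: g,
                             **{n: s.state[i] for i, n
                                in enumerate(species)},
                             "stability": s.stability})
        return pd.DataFrame(rows)


def scan_1d(params: ParameterSet, config: ModelConfig, param_name: str,
            prange: tuple, n_points: int = 60, n_starts: int = 30,
            seed: int = 0, fold_rel_precision: float = 1e-3
            ) -> BifurcationBranch:
    """Track all steady states across a parameter grid and locate folds."""
    if n_points < 3:
        raise ValueError("need at least 3 grid points")
    if not hasattr(params, param_name):
        raise ValueError(f"unknown parameter {param_name!r}")
    grid = np.linspace(prange[0], prange[1], n_points)
    all_states, warm = [], None
    for g in grid:
        p, sts = _states_at(params, config, param_name, g, warm,
                            n_starts, seed)
        if not sts:
            raise RuntimeError(
                f"no steady state found at {param_name}={g:.6g}")
        all_states.append(sts)
        warm = [s.state for s in sts]

    folds = []
    counts = [len(s) for s in all_states]
    for i in range(len(grid) - 1):
        if counts[i] == counts[i + 1]:
            continue
        lo, hi = grid[i], grid[i + 1]
        c_lo = counts[i]
        warm = [s.state for s in all_states[i] + all_states[i + 1]]
        while (hi - lo) > fold_rel_precision * max(abs(hi), 1e-12):
            mid = 0.5 * (lo + hi)
            _, sts = _states_at(params, config, param_name, mid, warm,
                                n_starts, seed)
            if len(sts) == c_lo:
                lo = mid
            else:
                hi = mid
            warm = warm + [s.state for s in sts]
        folds.append(0.5 * (lo + hi))
    return BifurcationBranch(param_name=param_name, grid=grid,
                             states=all_states, folds=folds, config=config)


@dataclass
class HysteresisResult:
    switched: bool
    threshold: float | None
    direction: str
    trace: list                    # (parameter value, tracked Zub)


def hysteresis_sweep(params: ParameterSet, config: ModelConfig,
                     param_name: str, prange: tuple, direction: str = "up",
                     step: float = 0.05) -> HysteresisResult:
    """Quasi-static sweep: relax to steady state, carry the state forward.

    Returns the parameter value at which the tracked branch jumps (the
    switch threshold); inside a bistable window the up-threshold exceeds
    the down-threshold.  If no jump occurs the ``switched`` flag is False.
    """
    if direction not in ("up", "down"):
        raise ValueError("direction must be 'up' or 'down'")
    lo, hi = min(prange), max(prange)
    values = np.arange(lo, hi + 0.5 * step, step)
    if direction == "down":
        values = values[::-1]

    p0 = params.replace(**{param_name: values[0]})
    start_states = find_steady_states(p0, config, n_starts=30, seed=0)
    if not start_states:
        raise RuntimeError("no steady state at the sweep start")
    stable = [s for s in start_states if s.is_stable]
    current = (stable[0] if stable else start_states[0]).state
    zi = config.species.index("Zub")

    trace = [(float(values[0]), float(current[zi]))]
    for v in values[1:]:
        p = params.replace(**{param_name: v})
        x, _res = _refine(_reduce(current, config), p, config)
        if x is None:
            jumped = True
        else:
            newstate = _expand(x, p, config)
            jumped = abs(newstate[zi] - current[zi]) > JUMP_THRESHOLD
            current = newstate
        trace.append((float(v), float(current[zi])))
        if jumped:
            return HysteresisResult(switched=True, threshold=float(v),
                                    direction=direction, trace=trace)
    return HysteresisResult(switched=False, threshold=None,
                            direction=direction, trace=trace)


@dataclass
class RegimeMap:
    """Regime label per cell of a (Bmi1_tot, USP7_tot) grid."""

    bmi1_grid: np.ndarray
    usp7_grid: np.ndarray
    labels: np.ndarray             # (n_usp7, n_bmi1) object array
    legend: tuple = ("monostable", "bistable", "oscillatory", "excitable",
                     "multistable", "other")

    def label_at(self, bmi1: float, usp7: float) -> str:
        i = int(np.argmin(np.abs(self.usp7_grid - usp7)))
        j = int(np.argmin(np.abs(self.bmi1_grid - bmi1)))
        return str(self.labels[i, j])

    def as_frame(self):
        import pandas as pd
        rows = [{"Bmi1_tot": b, "USP7_tot": u,
                 "regime": str(self.labels[i, j])}
                for i, u in enumerate(self.usp7_grid)
                for j, b in enumerate(self.bmi1_grid)]
        return pd.DataFrame(rows)


def regime_map(params: ParameterSet, config: ModelConfig,
               bmi1_range: tuple = (0.2, 6.0),
               usp7_range: tuple = (0.2, 4.0),
               resolution: tuple = (12, 8), n_starts: int = 25,
               seed: int = 0) -> RegimeMap:
    """Classify the dynamical regime over a (Bmi1_tot, USP7_tot) window.

    Classification is eigenvalue-based (see :func:`classify_regime`); a
    cell where enumeration fails is labelled ``other`` rather than aborting
    the map.
    """
    if min(bmi1_range) < 0 or min(usp7_range) < 0:
        raise ValueError("abundance ranges must be non-negative")
    bmi1 = np.linspace(bmi1_range[0], bmi1_range[1], resolution[0])
    usp7 = np.linspace(usp7_range[0], usp7_range[1], resolution[1])
    labels = np.empty((len(usp7), len(bmi1)), dtype=object)
    warm_row = [None] * len(bmi1)
    for i, u in enumerate(usp7):
        warm = None
        for j, b in enumerate(bmi1):
            p = params.replace(Bmi1_tot=float(b), USP7_tot=float(u))
            merged = list(warm or []) + list(warm_row[j] or [])
            try:
                sts = find_steady_states(p, config, n_starts=n_starts,
                                         seed=seed, warm_starts=merged)
                labels[i, j] = classify_regime(sts)
                warm = [s.state for s in sts]
                warm_row[j] = warm
            except Exception:
                labels[i, j] = "other"
                warm = None
    return RegimeMap(bmi1_grid=bmi1, usp7_grid=usp7, labels=labels)
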