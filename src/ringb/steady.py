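"""Steady-state enumeration, quasi-steady-state curves and stability.

The short-timescale model conserves three (MM) or four (mass-action) linear
combinations of species, so roots are sought in reduced coordinates with the
conservation laws eliminated; this removes the neutral eigen-directions that
would otherwise contaminate the stability call.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .model import (ModelConfig, ParameterSet, _fast_rhs, initial_state)

__all__ = ["SteadyState", "find_steady_states", "qss_curves",
           "NullclineCurve", "classify_regime", "reduced_jacobian"]

#: eigenvalue threshold for the stable/unstable call; real parts within
#: +/- EPS_EIG are flagged marginal.
EPS_EIG = 1e-9
#: relative Euclidean deduplication threshold for distinct roots.
DEDUP_RTOL = 1e-5
#: residual norm (normalized units / s) accepted for a converged root.
RESIDUAL_TOL = 1e-9

_RED_MM = ("Bd", "Rd", "Z", "Zub", "Ra", "Ru", "Hu")
_RED_MA = _RED_MM + ("C7",)


def _reduced_names(config: ModelConfig):
    return _RED_MA if config.variant == "mass-action" else _RED_MM


def _expand(x: np.ndarray, params: ParameterSet,
            config: ModelConfig) -> np.ndarray:
    """Reconstruct the full state from reduced coordinates."""
    if config.variant == "mass-action":
        Bd, Rd, Z, Zub, Ra, Ru, Hu, C7 = x
        U = params.USP7_tot - C7
        B = params.Bmi1_tot - Bd - Z - Zub - C7
        R = params.R1B_tot - Rd - Z - Zub - Ra - Ru - C7
        return np.array([B, Bd, R, Rd, Z, Zub, Ra, Ru,
                         params.H2A_tot - Hu, Hu, U, C7])
    Bd, Rd, Z, Zub, Ra, Ru, Hu = x
    B = params.Bmi1_tot - Bd - Z - Zub
    R = params.R1B_tot - Rd - Z - Zub - Ra - Ru
    return np.array([B, Bd, R, Rd, Z, Zub, Ra, Ru,
                     params.H2A_tot - Hu, Hu])


def _reduce(y: np.ndarray, config: ModelConfig) -> np.ndarray:
    species = config.species
    return np.array([y[species.index(n)] for n in _reduced_names(config)])


def _reduced_rhs(params: ParameterSet, config: ModelConfig):
    rhs = _fast_rhs(params, config)
    species = config.species
    sel = [species.index(n) for n in _reduced_names(config)]

    def f(x):
        return rhs(0.0, _expand(x, params, config))[sel]

    return f


def reduced_jacobian(x: np.ndarray, params: ParameterSet,
                     config: ModelConfig, rel_step: float = 1e-7
                     ) -> np.ndarray:
    """Central-difference Jacobian on the stoichiometric subspace."""
    f = _reduced_rhs(params, config)
    n = len(x)
    J = np.empty((n, n))
    for j in range(n):
        h = rel_step * max(1.0, abs(x[j]))
        e = np.zeros(n)
        e[j] = h
        J[:, j] = (f(x + e) - f(x - e)) / (2 * h)
    return J


@dataclass
class SteadyState:
    """A root of the ODE right-hand side with its local stability."""

    state: np.ndarray              # full species vector
    eigenvalues: np.ndarray        # reduced-Jacobian spectrum
    stability: str                 # "stable" | "unstable"
    residual_norm: float
    marginal: bool = False         # a real part within +/- EPS_EIG

    @property
    def is_stable(self) -> bool:
        return self.stability == "stable"

    def species(self, name: str, config: ModelConfig | None = None) -> float:
        from .model import SPECIES_MA, SPECIES_MM
        species = (config.species if config is not None else
                   (SPECIES_MA if len(self.state) == 12 else SPECIES_MM))
        return float(self.state[species.index(name)])


def _make_steady(x: np.ndarray, params: ParameterSet, config: ModelConfig,
                 residual: float) -> SteadyState:
    ev = np.linalg.eigvals(reduced_jacobian(x, params, config))
    stable = bool(np.all(ev.real < -EPS_EIG))
    marginal = bool(np.any(np.abs(ev.real) <= EPS_EIG))
    return SteadyState(state=_expand(x, params, config), eigenvalues=ev,
                       stability="stable" if stable else "unstable",
                       residual_norm=residual, marginal=marginal)


def _random_starts(params: ParameterSet, config: ModelConfig, n: int,
                   rng: np.random.Generator):
    """Uniform starts on the conservation simplex plus corner-biased ones."""
    Bt, Rt, Ht = params.Bmi1_tot, params.R1B_tot, params.H2A_tot
    ma = config.variant == "mass-action"
    starts = []
    # corner-biased: mass concentrated in one Ring1B species at a time
    for corner in ("Rd", "Zub", "Ra", "Ru", "Z", None):
        x = np.zeros(8 if ma else 7)
        names = _reduced_names(config)
        if corner is not None:
            x[names.index(corner)] = 0.9 * min(Rt, Bt) \
                if corner in ("Z", "Zub") else 0.9 * Rt
        if corner in (None, "Rd", "Ru", "Ra"):
            x[names.index("Bd")] = 0.5 * Bt
        x[names.index("Hu")] = 0.5 * Ht
        starts.append(x)
    starts = starts[:n]
    while len(starts) < n:
        wr = rng.dirichlet(np.ones(7 if ma else 6)) * Rt
        # wr: R, Rd, Z, Zub, Ra, Ru (, C7); complexes limited by Bmi1 too
        zz = wr[2] + wr[3] + (wr[6] if ma else 0.0)
        if zz > Bt:
            continue
        bfree = rng.uniform(0, 1)
        Bd = (Bt - zz) * (1 - bfree)
        x = [Bd, wr[1], wr[2], wr[3], wr[4], wr[5], rng.uniform(0, Ht)]
        if ma:
            c7 = min(wr[6], params.USP7_tot * rng.uniform(0, 1))
            x.append(c7)
            x[2] = wr[2]
        starts.append(np.array(x))
    return starts


def _refine(x0: np.ndarray, params: ParameterSet, config: ModelConfig):
    f = _reduced_rhs(params, config)
    sol = least_squares(lambda x: f(x), x0, method="lm",
                        xtol=1e-14, ftol=1e-14, max_nfev=4000)
    x = sol.x
    res = float(np.linalg.norm(f(x)))
    if res > RESIDUAL_TOL:
        return None, res
    if np.any(_expand(x, params, config) < -1e-8):
        return None, res
    return x, res


def find_steady_states(params: ParameterSet, config: ModelConfig,
                       n_starts: int = 50, seed: int = 0,
                       warm_starts=None) -> list[SteadyState]:
    """Enumerate steady states by seeded multi-start root search.

    Roots are deduplicated at relative distance ``DEDUP_RTOL`` and returned
    sorted by their Zub concentration, each with the Jacobian spectrum on
    the stoichiometric subspace and a stability label.  ``warm_starts`` may
    carry full state vectors (e.g. from a neighbouring parameter point) that
    are tried first.  An empty result issues a warning, never silence.
    """
    params.validate(config)
    rng = np.random.default_rng(seed)
    starts = [_reduce(np.asarray(w), config) for w in (warm_starts or [])]
    starts += _random_starts(params, config, n_starts, rng)
    roots, residuals = [], []
    for x0 in starts:
        x, res = _refine(x0, params, config)
        if x is None:
            continue
        if not any(np.linalg.norm(x - r) / (1 + np.linalg.norm(r))
                   < DEDUP_RTOL for r in roots):
            roots.append(x)
            residuals.append(res)
    order = np.argsort([r[3] for r in roots])   # Zub is reduced coord 3
    out = [_make_steady(roots[i], params, config, residuals[i])
           for i in order]
    if not out:
        warnings.warn("no steady state found from any start",
                      RuntimeWarning, stacklevel=2)
    return out


@dataclass
class NullclineCurve:
    """Quasi-steady-state response of one species against a clamped one."""

    clamped: str                   # species held fixed across the grid
    responding: str                # species whose QSS value is reported
    grid: np.ndarray
    values: np.ndarray             # NaN where the QSS solve failed
    failed: np.ndarray             # boolean flags, never interpolated


def _clamped_qss(params: ParameterSet, config: ModelConfig, clamp: str,
                 respond: str, grid: np.ndarray) -> NullclineCurve:
    names = list(_reduced_names(config))
    ci = names.index(clamp)
    free = [i for i in range(len(names)) if i != ci]
    f_all = _reduced_rhs(params, config)
    # drop the clamped species' own balance equation; solve the others
    keep_eq = [i for i in range(len(names)) if i != ci]

    vals = np.full(len(grid), np.nan)
    failed = np.zeros(len(grid), dtype=bool)
    xfull = np.zeros(len(names))
    xfull[names.index("Bd")] = 0.4 * params.Bmi1_tot
    xfull[names.index("Rd")] = 0.5 * params.R1B_tot
    warm = xfull[free]
    for i, g in enumerate(grid):
        def resid(xf, g=g):
            x = np.zeros(len(names))
            x[ci] = g
            x[free] = xf
            return f_all(x)[keep_eq]

        best = None
        for x0 in (warm, np.full(len(free), 0.05),
                   np.full(len(free), 0.3)):
            sol = least_squares(resid, x0, method="lm", xtol=1e-13,
                                ftol=1e-13, max_nfev=2000)
            r = float(np.linalg.norm(resid(sol.x)))
            if r < 1e-8:
                best = sol.x
                break
        if best is None:
            failed[i] = True
            continue
        warm = best
        x = np.zeros(len(names))
        x[ci] = g
        x[free] = best
        y = _expand(x, params, config)
        vals[i] = y[config.species.index(respond)]
    return NullclineCurve(clamped=clamp, responding=respond,
                          grid=np.asarray(grid), values=vals, failed=failed)


def qss_curves(params: ParameterSet, config: ModelConfig,
               grid: np.ndarray, partition: tuple = ("Rd", "Zub")
               ) -> tuple[NullclineCurve, NullclineCurve]:
    """The two quasi-steady-state curves on the (Rd, Zub) plane.

    The first curve clamps Rd and reports the QSS Zub; the second clamps
    Zub and reports the QSS Rd.  Intersections of the two curves coincide
    with the full-system steady states (each curve satisfies all balance
    equations except the clamped species' own).  The clamped pair is
    configurable via ``partition``.
    """
    a, b = partition
    grid = np.asarray(grid, dtype=float)
    c1 = _clamped_qss(params, config, a, b, grid)
    c2 = _clamped_qss(params, config, b, a, grid)
    return c1, c2


def classify_regime(steady_list: list[SteadyState],
                    params: ParameterSet | None = None) -> str:
    """Label a parameter point from its steady-state count and stability.

    monostable: one stable state; bistable: two stable separated by one
    unstable; oscillatory: a single unstable state; excitable: one stable
    plus two unstable; three or more stable states: multistable; anything
    else: other.
    """
    if not steady_list:
        raise ValueError("cannot classify an empty steady-state list")
    ns = sum(s.is_stable for s in steady_list)
    nu = len(steady_list) - ns
    if ns >= 3:
        return "multistable"
    if (ns, nu) == (1, 0):
        return "monostable"
    if (ns, nu) == (2, 1):
        return "bistable"
    if (ns, nu) == (0, 1):
        return "oscillatory"
    if (ns, nu) == (1, 2):
        return "excitable"
    return "other"
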