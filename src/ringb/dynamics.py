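"""Time-course integration, oscillation detection and excitability.

Integration uses LSODA (switching stiff/non-stiff) at tight tolerances
(rtol 1e-8, atol 1e-10 by default); relaxation oscillations in this system
alternate fast ubiquitination bursts with slow reservoir recovery, which is
exactly the stiffness profile LSODA is built for.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp
from scipy.signal import find_peaks

from .model import ModelConfig, ParameterSet, _fast_rhs, conserved_totals

__all__ = ["Trajectory", "OscillationReport", "PerturbationSpec",
           "simulate", "detect_oscillations", "excitability_threshold",
           "overshoot_metrics"]

RTOL = 1e-8
ATOL = 1e-10


@dataclass
class Trajectory:
    """Time-stamped states from one integration run."""

    t: np.ndarray                  # seconds
    y: np.ndarray                  # (n_species, n_times)
    params: ParameterSet
    config: ModelConfig

    def species(self, name: str) -> np.ndarray:
        return self.y[self.config.species.index(name)]

    def final_state(self) -> np.ndarray:
        return self.y[:, -1].copy()

    def conservation_drift(self) -> dict:
        """Max relative drift of each conserved total over the run."""
        first = conserved_totals(self.y[:, 0], self.config)
        out = {}
        for k, v0 in first.items():
            vals = np.array([conserved_totals(self.y[:, i], self.config)[k]
                             for i in range(self.y.shape[1])])
            out[k] = float(np.max(np.abs(vals - v0)) / max(abs(v0), 1e-12))
        return out

    def as_frame(self):
        import pandas as pd
        return pd.DataFrame({"time": self.t,
                             **{n: self.y[i] for i, n
                                in enumerate(self.config.species)}})


def simulate(params: ParameterSet, config: ModelConfig, init: np.ndarray,
             t_end: float, t_eval=None, rtol: float = RTOL,
             atol: float = ATOL, events=None) -> Trajectory:
    """Integrate the model from ``init`` to ``t_end`` seconds."""
    init = np.asarray(init, dtype=float)
    if t_end <= 0:
        raise ValueError("t_end must be positive")
    if np.any(init < -1e-12):
        raise ValueError("initial state has negative concentrations")
    params.validate(config)
    rhs = _fast_rhs(params, config)
    if t_eval is None:
        t_eval = np.linspace(0.0, t_end, 1000)
    sol = solve_ivp(rhs, (0.0, float(t_end)), init, method="LSODA",
                    t_eval=np.asarray(t_eval, dtype=float),
                    rtol=rtol, atol=atol, events=events)
    if not sol.success:
        raise RuntimeError(
            f"integration failed at t={sol.t[-1] if len(sol.t) else 0:.3g}s:"
            f" {sol.message}")
    return Trajectory(t=sol.t, y=sol.y, params=params, config=config)


@dataclass
class OscillationReport:
    """Period, amplitudes and phase relations of a (putative) limit cycle."""

    is_oscillatory: bool
    period: float | None = None                  # s
    period_cv: float | None = None               # inter-peak interval CV
    amplitudes: dict = field(default_factory=dict)   # peak-to-trough
    phase_lags: dict = field(default_factory=dict)   # vs Zub, cycle fraction
    sustain_ratio: float | None = None


def _phase_lag(ref: np.ndarray, sig: np.ndarray, dt: float,
               period: float) -> float:
    """Lag of ``sig`` behind ``ref`` as a fraction of the period.

    Cross-correlation restricted to +/- one period; positive means ``sig``
    peaks after ``ref``.
    """
    n = len(ref)
    a = ref - ref.mean()
    b = sig - sig.mean()
    max_shift = int(round(period / dt))
    shifts = np.arange(-max_shift, max_shift + 1)
    cc = [np.dot(a[max(0, -s):n - max(0, s)],
                 b[max(0, s):n - max(0, -s)]) for s in shifts]
    best = shifts[int(np.argmax(cc))]
    frac = best * dt / period
    return float(frac - np.round(frac))   # wrap to (-0.5, 0.5]


def detect_oscillations(traj: Trajectory, transient_fraction: float = 0.3,
                        species=("Zub", "Rd", "Ra"),
                        sustain_threshold: float = 0.95,
                        min_peaks: int = 5) -> OscillationReport:
    """Peak-based oscillation analysis after discarding the transient.

    Sustained oscillation requires at least ``min_peaks`` peaks of the Zub
    signal after the transient, inter-peak intervals with CV < 0.05, and a
    last/first peak-to-peak amplitude ratio above ``sustain_threshold``
    (non-decaying).
    """
    i0 = int(len(traj.t) * transient_fraction)
    if len(traj.t) - i0 < 10:
        raise ValueError("trajectory too short after transient discard")
    t = traj.t[i0:]
    dt = float(np.median(np.diff(t)))
    z = traj.species("Zub")[i0:]
    amp = float(z.max() - z.min())
    if amp < 1e-6:
        return OscillationReport(is_oscillatory=False, sustain_ratio=0.0)
    peaks, props = find_peaks(z, prominence=0.2 * amp)
    if len(peaks) < min_peaks:
        return OscillationReport(is_oscillatory=False, sustain_ratio=0.0)
    intervals = np.diff(t[peaks])
    period = float(np.mean(intervals))
    period_cv = float(np.std(intervals) / period)
    # drop a possibly truncated peak at the trajectory end, then compare
    # early vs late prominences (median over 3) for the sustain criterion
    prom = props["prominences"]
    if t[-1] - t[peaks[-1]] < 0.5 * period and len(peaks) > min_peaks:
        prom = prom[:-1]
    k = min(3, len(prom) // 2)
    sustain = (float(np.median(prom[-k:]) / np.median(prom[:k]))
               if np.median(prom[:k]) > 0 else 0.0)
    is_osc = (period_cv < 0.05) and (sustain > sustain_threshold)

    amplitudes, lags = {}, {}
    for name in species:
        sig = traj.species(name)[i0:]
        amplitudes[name] = float(sig.max() - sig.min())
        if name != "Zub" and is_osc:
            lags[name] = _phase_lag(z, sig, dt, period)
    return OscillationReport(is_oscillatory=bool(is_osc),
                             period=period if is_osc else None,
                             period_cv=period_cv, amplitudes=amplitudes,
                             phase_lags=lags, sustain_ratio=sustain)


@dataclass(frozen=True)
class PerturbationSpec:
    """A transient perturbation applied to a resting steady state.

    ``state-increment``: an instantaneous concentration increment on one
    species (``magnitude`` in concentration units).  ``parameter-pulse``: a
    rectangular fold-change pulse on one rate constant (``magnitude`` as the
    fold factor, e.g. 1.4 for +40%), starting at ``start`` for ``duration``
    seconds; the parameter is restored exactly at pulse end.
    """

    kind: str                      # "state-increment" | "parameter-pulse"
    target: str                    # species or parameter name
    magnitude: float
    start: float = 500.0
    duration: float | None = None

    def __post_init__(self):
        if self.kind not in ("state-increment", "parameter-pulse"):
            raise ValueError(f"unknown perturbation kind {self.kind!r}")
        if self.kind == "parameter-pulse" and (self.duration is None
                                               or self.duration <= 0):
            raise ValueError("parameter-pulse needs a positive duration")


def _respond(params: ParameterSet, config: ModelConfig,
             rest: np.ndarray, spec: PerturbationSpec, value: float,
             t_end: float) -> Trajectory:
    """Trajectory of the response to one perturbation instance.

    ``value`` overrides the magnitude (state increment) or duration
    (parameter pulse), which is the bisected quantity.
    """
    species = config.species
    if spec.kind == "state-increment":
        y0 = rest.copy()
        y0[species.index(spec.target)] += value
        return simulate(params, config, y0, t_end)
    # parameter pulse: piecewise integration, parameter restored exactly
    pulsed = params.replace(
        **{spec.target: getattr(params, spec.target) * spec.magnitude})
    pre = simulate(params, config, rest, spec.start,
                   t_eval=np.linspace(0, spec.start, 64))
    during = simulate(pulsed, config, pre.final_state(), value,
                      t_eval=np.linspace(0, value, 128))
    after = simulate(params, config, during.final_state(),
                     t_end - spec.start - value)
    t = np.concatenate([pre.t, spec.start + during.t[1:],
                        spec.start + value + after.t[1:]])
    y = np.concatenate([pre.y, during.y[:, 1:], after.y[:, 1:]], axis=1)
    return Trajectory(t=t, y=y, params=params, config=config)


def _peak_deviation(traj: Trajectory, rest: np.ndarray,
                    species_name: str = "Zub") -> float:
    i = traj.config.species.index(species_name)
    return float(np.max(np.abs(traj.y[i] - rest[i])))


def excitability_threshold(params: ParameterSet, config: ModelConfig,
                           spec: PerturbationSpec, bracket: tuple,
                           rest: np.ndarray | None = None,
                           t_end: float = 20000.0,
                           response_excess: float = 0.02,
                           rel_precision: float = 1e-3) -> dict:
    """All-or-none threshold of an excitable steady state, by bisection.

    A response is classified a large excursion when the peak Zub deviation
    *exceeds the applied increment itself* (state perturbations) or the
    sub-threshold response at the lower bracket end (parameter pulses) by
    more than ``response_excess`` concentration units: a sub-threshold
    response decays monotonically, so its peak equals the kick, while an
    over-threshold response adds an autocatalytic excursion of roughly
    fixed size on top -- there are no intermediate responses to confuse
    the split.  The bracket ends must classify differently.  Returns the
    threshold with the bracketing responses.
    """
    if rest is None:
        from .steady import find_steady_states
        states = [s for s in find_steady_states(params, config, seed=0)
                  if s.is_stable]
        if not states:
            raise ValueError("no stable resting state at this parameter "
                             "point; excitability is undefined")
        rest = states[0].state

    lo, hi = float(bracket[0]), float(bracket[1])

    def classify(value):
        if value == 0:
            return False, 0.0
        traj = _respond(params, config, rest, spec, value, t_end)
        dev = _peak_deviation(traj, rest)
        if spec.kind == "state-increment":
            ref = abs(value)
        else:
            ref = classify.sub_ref
        return dev - ref > response_excess, dev

    if spec.kind == "parameter-pulse":
        # reference amplitude: the sub-threshold response at the low end
        traj_lo = _respond(params, config, rest, spec, lo, t_end)
        classify.sub_ref = max(_peak_deviation(traj_lo, rest), 1e-9)

    over_lo, dev_lo = classify(lo)
    over_hi, dev_hi = classify(hi)
    if over_lo == over_hi:
        raise ValueError(
            f"bracket ends classify identically "
            f"({'over' if over_lo else 'sub'}-threshold at both "
            f"{lo} and {hi}); widen the bracket")
    while (hi - lo) > rel_precision * hi:
        mid = 0.5 * (lo + hi)
        over, _ = classify(mid)
        if over == over_hi:
            hi = mid
        else:
            lo = mid
    return {"threshold": 0.5 * (lo + hi), "bracket": (lo, hi),
            "sub_response": dev_lo if not over_lo else dev_hi,
            "over_response": dev_hi if over_hi else dev_lo,
            "rest": rest}


def overshoot_metrics(traj: Trajectory, baseline: np.ndarray,
                      recovery_band: float = 0.05) -> dict:
    """Per-species peak deviation, time to peak and recovery time.

    Recovery time is when the species re-enters (and stays within) a band
    of ``recovery_band`` times the peak deviation around the baseline;
    species that never settle get ``recovered=False``.
    """
    out = {}
    for i, name in enumerate(traj.config.species):
        dev = traj.y[i] - baseline[i]
        adev = np.abs(dev)
        ipk = int(np.argmax(adev))
        peak = float(adev[ipk])
        entry = {"peak_deviation": peak,
                 "time_to_peak": float(traj.t[ipk]),
                 "recovered": True, "recovery_time": 0.0}
        if peak > 0:
            band = recovery_band * peak
            outside = adev > band
            if outside[-1]:
                entry["recovered"] = False
                entry["recovery_time"] = float("inf")
            else:
                last_out = np.nonzero(outside)[0]
                entry["recovery_time"] = (
                    float(traj.t[last_out[-1] + 1]) if len(last_out)
                    else 0.0)
        out[name] = entry
    return out
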