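"""Integration, oscillation detection, excitability and overshoots."""

import numpy as np
import pytest

from ringb import (EXCITABLE_POINT, PerturbationSpec, Trajectory,
                   detect_oscillations, excitability_threshold,
                   find_steady_states, initial_state, overshoot_metrics,
                   simulate)


@pytest.fixture(scope="module")
def excitable_rest(oscillatory):
    p, c = oscillatory
    p = p.replace(**EXCITABLE_POINT)
    states = [s for s in find_steady_states(p, c, n_starts=40, seed=0)
              if s.is_stable]
    assert states, "excitable operating point lost its rest state"
    return p, c, states[0].state


class TestSimulate:
    def test_high_bmi1ub_start_reaches_the_low_activity_state(self,
                                                              bistable):
        # inside the bistable window, starting with Bmi1 mostly
        # ubiquitinated leaves Ring1B unprotected: low Zub, high Rd
        p, c = bistable
        y0 = initial_state(c, Bd=2.45, Rd=0.05, R=0.9, Zub=0.05, H=1.0)
        tr = simulate(p, c, y0, 40000.0)
        f = tr.final_state()
        assert f[c.species.index("Zub")] < 0.1
        assert f[c.species.index("Rd")] > 0.5

    def test_high_free_bmi1_start_reaches_the_high_activity_state(
            self, bistable):
        p, c = bistable
        y0 = initial_state(c, Bd=1.08, B=1.1, Rd=0.12, R=0.1, Z=0.2,
                           Zub=0.12, Ra=0.44, Ru=0.02, H=1.0)
        tr = simulate(p, c, y0, 40000.0)
        f = tr.final_state()
        assert f[c.species.index("Zub")] > 0.3
        assert f[c.species.index("Rd")] < 0.4

    def test_stable_steady_state_stays_put(self, bistable, anchor_states):
        p, c = bistable
        rest = anchor_states[0].state
        tr = simulate(p, c, rest, 3600.0)
        assert np.max(np.abs(tr.y - rest[:, None])) < 1e-6

    def test_conservation_along_trajectories(self, bistable):
        p, c = bistable
        y0 = initial_state(c, Bd=2.5, R=1.0, H=1.0)
        tr = simulate(p, c, y0, 20000.0)
        assert max(tr.conservation_drift().values()) < 1e-6

    def test_integration_rejects_bad_inputs(self, bistable):
        p, c = bistable
        with pytest.raises(ValueError):
            simulate(p, c, initial_state(c, R=1.0), -5.0)
        y0 = initial_state(c, R=1.0)
        y0[0] = -1.0
        with pytest.raises(ValueError):
            simulate(p, c, y0, 10.0)


class TestDetectOscillations:
    def test_constant_trajectory_is_not_oscillatory(self, bistable,
                                                    anchor_states):
        p, c = bistable
        tr = simulate(p, c, anchor_states[0].state, 5000.0,
                      t_eval=np.linspace(0, 5000, 600))
        assert not detect_oscillations(tr).is_oscillatory

    def test_known_sinusoid_period_is_recovered(self, bistable):
        p, c = bistable
        t = np.linspace(0, 10000, 2500)
        period = 700.0
        y = np.tile(0.2 * np.ones_like(t), (10, 1))
        y[c.species.index("Zub")] = 0.3 + 0.1 * np.sin(
            2 * np.pi * t / period)
        tr = Trajectory(t=t, y=y, params=p, config=c)
        rep = detect_oscillations(tr)
        assert rep.is_oscillatory
        assert rep.period == pytest.approx(period, abs=t[1] - t[0])

    def test_sustained_oscillation_at_the_oscillatory_anchor(
            self, oscillatory):
        p, c = oscillatory
        p = p.replace(USP7_tot=2.0, Bmi1_tot=3.25)
        y0 = initial_state(c, Bd=3.25, R=1.0, H=1.0)
        tr = simulate(p, c, y0, 80000.0,
                      t_eval=np.linspace(0, 80000, 8000))
        rep = detect_oscillations(tr)
        assert rep.is_oscillatory
        assert rep.period > 0 and rep.period_cv < 0.05
        assert rep.sustain_ratio > 0.95
        # the active free form is released from Zub, so it peaks slightly
        # after the complex
        assert 0 < rep.phase_lags["Ra"] < 0.15

    def test_too_short_trajectory_is_an_error(self, bistable,
                                              anchor_states):
        p, c = bistable
        tr = simulate(p, c, anchor_states[0].state, 10.0,
                      t_eval=np.linspace(0, 10, 8))
        with pytest.raises(ValueError, match="too short"):
            detect_oscillations(tr)


class TestExcitability:
    def test_zub_increment_threshold_is_all_or_none(self, excitable_rest):
        p, c, rest = excitable_rest
        spec = PerturbationSpec(kind="state-increment", target="Zub",
                                magnitude=0.0)
        res = excitability_threshold(p, c, spec, bracket=(0.005, 0.05),
                                     rest=rest, t_end=15000.0)
        assert 0.005 < res["threshold"] < 0.05
        # no intermediate responses: across the final bracket the
        # excursion is many times the sub-threshold response
        assert res["over_response"] / res["sub_response"] > 5

    def test_threshold_agrees_with_dense_sweep_oracle(self,
                                                      excitable_rest):
        p, c, rest = excitable_rest
        zi = c.species.index("Zub")
        spec = PerturbationSpec(kind="state-increment", target="Zub",
                                magnitude=0.0)
        res = excitability_threshold(p, c, spec, bracket=(0.005, 0.05),
                                     rest=rest, t_end=15000.0)
        mags = np.linspace(0.005, 0.05, 40)
        devs = []
        for m in mags:
            y0 = rest.copy()
            y0[zi] += m
            tr = simulate(p, c, y0, 15000.0)
            devs.append(np.max(np.abs(tr.species("Zub") - rest[zi])))
        fired = (np.array(devs) - mags) > 0.02
        assert fired[-1] and not fired[0]
        sweep_thr = mags[np.argmax(fired)]
        assert abs(res["threshold"] - sweep_thr) <= mags[1] - mags[0]

    def test_identical_bracket_classes_raise(self, excitable_rest):
        p, c, rest = excitable_rest
        spec = PerturbationSpec(kind="state-increment", target="Zub",
                                magnitude=0.0)
        with pytest.raises(ValueError, match="classify identically"):
            excitability_threshold(p, c, spec, bracket=(0.0005, 0.001),
                                   rest=rest, t_end=6000.0)

    def test_parameter_pulse_has_a_duration_threshold(self,
                                                      excitable_rest):
        p, c, rest = excitable_rest
        spec = PerturbationSpec(kind="parameter-pulse", target="k6a",
                                magnitude=1.4, start=500.0, duration=1.0)
        res = excitability_threshold(p, c, spec, bracket=(2.0, 120.0),
                                     rest=rest, t_end=15000.0)
        assert 2.0 < res["threshold"] < 120.0

    def test_pulse_response_returns_to_the_same_rest_state(
            self, excitable_rest):
        # a parameter pulse conserves the totals, so the excursion must
        # come back to the very same steady state
        from ringb.dynamics import _respond
        p, c, rest = excitable_rest
        spec = PerturbationSpec(kind="parameter-pulse", target="k6a",
                                magnitude=1.4, start=500.0, duration=60.0)
        tr = _respond(p, c, rest, spec, 60.0, 120000.0)
        zi = c.species.index("Zub")
        assert np.max(np.abs(tr.species("Zub") - rest[zi])) > 0.05
        assert np.max(np.abs(tr.y[:, -1] - rest)) < 1e-4

    def test_increment_response_returns_to_rest_on_its_manifold(
            self, excitable_rest):
        # a Zub increment changes the conserved totals, so the return
        # point is the steady state of the perturbed totals
        p, c, rest = excitable_rest
        zi = c.species.index("Zub")
        y0 = rest.copy()
        y0[zi] += 0.02
        tr = simulate(p, c, y0, 200000.0)
        p2 = p.replace(Bmi1_tot=p.Bmi1_tot + 0.02,
                       R1B_tot=p.R1B_tot + 0.02)
        rest2 = [s for s in find_steady_states(p2, c, n_starts=30, seed=0)
                 if s.is_stable][0].state
        assert np.max(np.abs(tr.y[:, -1] - rest2)) < 1e-4

    def test_h2a_ub_shows_the_same_dichotomy(self, excitable_rest):
        p, c, rest = excitable_rest
        hi = c.species.index("Hu")
        zi = c.species.index("Zub")
        responses = {}
        for m in (0.005, 0.04):
            y0 = rest.copy()
            y0[zi] += m
            tr = simulate(p, c, y0, 15000.0)
            responses[m] = np.max(np.abs(tr.species("Hu") - rest[hi]))
        assert responses[0.04] / responses[0.005] > 5


class TestOvershootMetrics:
    def test_baseline_trajectory_has_zero_deviation(self, bistable,
                                                    anchor_states):
        p, c = bistable
        rest = anchor_states[0].state
        tr = simulate(p, c, rest, 1000.0)
        m = overshoot_metrics(tr, rest)
        assert all(v["peak_deviation"] < 1e-7 for v in m.values())

    def test_overshoot_recovery_is_slower_than_the_rise(self,
                                                        excitable_rest):
        from ringb.dynamics import _respond
        p, c, rest = excitable_rest
        spec = PerturbationSpec(kind="parameter-pulse", target="k6a",
                                magnitude=1.4, start=500.0, duration=60.0)
        tr = _respond(p, c, rest, spec, 60.0, 60000.0)
        m = overshoot_metrics(tr, rest)
        assert m["Rd"]["recovered"]
        assert m["Rd"]["recovery_time"] > m["Rd"]["time_to_peak"]

    def test_unrecovered_flag_when_trajectory_ends_off_baseline(
            self, bistable):
        p, c = bistable
        y0 = initial_state(c, Bd=2.5, R=1.0, H=1.0)
        tr = simulate(p, c, y0, 500.0)
        m = overshoot_metrics(tr, tr.y[:, 0])
        assert not m["Bd"]["recovered"]
        assert m["Bd"]["recovery_time"] == float("inf")


def test_oscillation_period_is_robust_to_tighter_tolerances(oscillatory):
    p, c = oscillatory
    p = p.replace(USP7_tot=2.0, Bmi1_tot=3.25)
    y0 = initial_state(c, Bd=3.25, R=1.0, H=1.0)
    periods = []
    for rtol, atol in ((1e-8, 1e-10), (5e-9, 5e-11)):
        tr = simulate(p, c, y0, 60000.0, rtol=rtol, atol=atol,
                      t_eval=np.linspace(0, 60000, 6000))
        periods.append(detect_oscillations(tr).period)
    assert abs(periods[1] - periods[0]) / periods[0] < 0.01
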