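import numpy as np
import pytest

from ringb import (default_config, default_parameters, find_steady_states,
                   initial_state, scan_1d)


@pytest.fixture(scope="session")
def bistable():
    """Calibrated bistable MM set with its config."""
    return default_parameters(), default_config()


@pytest.fixture(scope="session")
def oscillatory():
    """Calibrated oscillatory MM set (DUB competition on) with config."""
    return (default_parameters(source="oscillatory"),
            default_config("oscillatory"))


@pytest.fixture(scope="session")
def mass_action():
    """Mass-action counterpart of the bistable set."""
    return (default_parameters("mass-action", "table_s2"),
            default_config("table_s2"))


@pytest.fixture(scope="session")
def bmi1_branch(bistable):
    """Bmi1 scan of the bistable set, shared across fold/hysteresis tests."""
    p, c = bistable
    return scan_1d(p, c, "Bmi1_tot", (0.5, 5.0), n_points=40, seed=0)


@pytest.fixture(scope="session")
def anchor_states(bistable):
    p, c = bistable
    return find_steady_states(p, c, n_starts=40, seed=0)


def rng_state(config, params, **kw):
    """Random admissible state respecting the conserved totals."""
    rng = kw.pop("rng", np.random.default_rng(0))
    w = rng.dirichlet(np.ones(6)) * params.R1B_tot
    R, Rd, Z, Zub, Ra, Ru = w
    if Z + Zub > params.Bmi1_tot:
        Z = Zub = 0.1 * params.Bmi1_tot
    bfree = rng.uniform(0, params.Bmi1_tot - Z - Zub)
    Bd = params.Bmi1_tot - Z - Zub - bfree
    Hu = rng.uniform(0, params.H2A_tot)
    return initial_state(config, B=bfree, Bd=Bd, R=R, Rd=Rd, Z=Z, Zub=Zub,
                         Ra=Ra, Ru=Ru, H=params.H2A_tot - Hu, Hu=Hu)
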