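import numpy as np
import pytest

from coopdyn.task import ScheduleConfig, generate_partner_schedule
from coopdyn.models import simulate_agent

M8_PARAMS = dict(alpha_pos=0.4, alpha_neg=0.2, omega=2.0, beta=2.0)


@pytest.fixture(scope="session")
def default_cfg():
    return ScheduleConfig(seed=1)


@pytest.fixture(scope="session")
def mini_cfg():
    """Short schedule (30 trials, 3 volatile blocks of 5) for fast tests."""
    return ScheduleConfig(n_trials=30, volatile_block_len=5, probe_interval=15, seed=1)


@pytest.fixture(scope="session")
def m8_session(default_cfg):
    """One 120-trial M8 session with known generating parameters."""
    schedule = generate_partner_schedule(default_cfg)
    session, trace = simulate_agent("M8", M8_PARAMS, schedule, rng=7)
    return session, trace


def random_params(model, rng):
    """Uniform draw within a model's parameter bounds."""
    return {
        name: float(rng.uniform(lo, hi)) for name, (lo, hi) in
        zip(model.param_names, model.bounds)
    }
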