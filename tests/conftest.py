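import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from chcmotif.behavior import BehaviorTrace
from chcmotif.synthetic import BehaviorSimConfig, simulate_behavior


def make_trace(speed, sample_rate=100.0, fb=None, rl=None, x=None, y=None, accel=None):
    """Toy BehaviorTrace from a speed profile (heading due right by default)."""
    speed = np.asarray(speed, dtype=float)
    n = speed.size
    t = np.arange(n) / sample_rate
    rl = speed.copy() if rl is None else np.asarray(rl, float)
    fb = np.zeros(n) if fb is None else np.asarray(fb, float)
    return BehaviorTrace(
        time_s=t,
        fb_speed=fb,
        rl_speed=rl,
        x=np.zeros(n) if x is None else np.asarray(x, float),
        y=np.zeros(n) if y is None else np.asarray(y, float),
        sample_rate=sample_rate,
        speed=speed,
        accel=accel,
    )


@pytest.fixture(scope="session")
def sim_behavior():
    """A 200-s simulated session shared across tests."""
    return simulate_behavior(BehaviorSimConfig(duration_s=200.0, seed=11))


@pytest.fixture(scope="session")
def sim_behavior_movement(sim_behavior):
    trace, truth = sim_behavior
    movement = truth.frame_state_true == "movement"
    return trace, truth, movement
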