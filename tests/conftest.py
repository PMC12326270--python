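import numpy as np
import pytest

from mitoflight.respirometry import RespirationStates
from mitoflight.synthetic import (
    CohortSimParams,
    TraceSimParams,
    TrajectorySimParams,
    simulate_cohort,
    simulate_o2k_trace,
    simulate_takeoff,
)


@pytest.fixture(scope="session")
def projectile_series():
    """Noiseless ballistic take-off at 60 fps (closed-form oracle available)."""
    return simulate_takeoff(
        TrajectorySimParams(mass=0.025, fps=60.0, n_frames=30,
                            launch_speed=3.0, launch_angle=0.6,
                            coord_noise_sd=0.0, seed=0)
    )


@pytest.fixture(scope="session")
def noiseless_trace():
    return simulate_o2k_trace(TraceSimParams(noise_sd=0.0, seed=0))


@pytest.fixture(scope="session")
def default_cohort():
    return simulate_cohort(CohortSimParams(seed=42))


def make_states(routine_c, leak_c, ets_c=10.0, **kw):
    """Corrected respiration states with arbitrary values, for ratio tests."""
    return RespirationStates(
        routine=routine_c, leak=leak_c, ets=ets_c, nonmito=0.0,
        routine_c=routine_c, leak_c=leak_c, ets_c=ets_c,
        oxphos_c=routine_c - leak_c, **kw,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
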