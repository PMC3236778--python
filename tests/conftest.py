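import numpy as np
import pytest
from hypothesis import settings, HealthCheck

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from smtpm.substrate import fork_ac90, mimic_unwound
from smtpm.simulate import SimulationConfig, simulate_bead_trajectory
from smtpm.processing import Trajectory


@pytest.fixture(scope="session")
def fork():
    return fork_ac90()


@pytest.fixture(scope="session")
def mimic():
    return mimic_unwound()


@pytest.fixture
def rng():
    return np.random.default_rng(0)


def make_trajectory(x, y, frame_rate=30.0, recorded=None, bead_id="b0"):
    """Deterministic trajectory from explicit coordinate arrays."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if recorded is None:
        recorded = np.ones(n, dtype=bool)
    return Trajectory(
        bead_id=bead_id,
        times=np.arange(n) / frame_rate,
        x=x,
        y=y,
        recorded=recorded,
        frame_rate=frame_rate,
    )


@pytest.fixture
def stationary_config():
    """Short stationary recording with fast tether relaxation (so windowed
    variance is nearly unbiased) and no bead-to-bead spread."""
    return SimulationConfig(
        duration=120.0, tau=0.01, drift=0.0, sigma0_sd=0.0, dead_time=0.0
    )
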