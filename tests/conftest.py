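import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

from spindlescale.params import STAGE_TABLE, DEFAULT_MOTORS, DEFAULT_DRAGS, DEFAULT_LAW  # noqa: E402
from spindlescale.model import simulate_spindle  # noqa: E402


@pytest.fixture(scope="session")
def stage8_trajectory():
    """One 8-cell simulation at reduced mesh, reused across tests."""
    return simulate_spindle(STAGE_TABLE[8], n_patches=256, t_end=300.0)


@pytest.fixture(scope="session")
def table2_trajectories():
    """Full-resolution simulations of all six per-stage configurations."""
    return {n: simulate_spindle(cfg) for n, cfg in STAGE_TABLE.items()}


@pytest.fixture(scope="session")
def default_params():
    return DEFAULT_MOTORS, DEFAULT_DRAGS, DEFAULT_LAW


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
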