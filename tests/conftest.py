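import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from fasym import (
    LandmarkScheme,
    ObjectSymmetryModel,
    SimulationParams,
    simulate_dataset,
)

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def toy_scheme() -> LandmarkScheme:
    """Two bilateral pairs + one midline landmark (smallest useful scheme)."""
    return LandmarkScheme(n_landmarks=5, pairs=((0, 1), (2, 3)), midline=(4,))


@pytest.fixture(scope="session")
def small_params() -> SimulationParams:
    return SimulationParams(n=12, r=2, p=3, u=2, seed=11)


@pytest.fixture(scope="session")
def small_dataset(small_params):
    return simulate_dataset(small_params)


@pytest.fixture(scope="session")
def small_results(small_dataset):
    return ObjectSymmetryModel(small_dataset).fit()


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(20230811)
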