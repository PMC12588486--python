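import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from gdbn import TimeSeries, VARProcess, fixture_process, fold, simulate_series

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def k5_process() -> VARProcess:
    return fixture_process("k5", seed=7)


@pytest.fixture(scope="session")
def k5_series(k5_process) -> TimeSeries:
    return simulate_series(k5_process, T=400, seed=11)


@pytest.fixture(scope="session")
def k5_folded(k5_series):
    return fold(k5_series, p=1)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20260928)


def random_series(rng: np.random.Generator, T: int, k: int) -> TimeSeries:
    """Plain iid-Gaussian series helper shared across tests."""
    names = tuple(f"V{i}" for i in range(k))
    return TimeSeries(rng.standard_normal((T, k)), names)
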