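import numpy as np
import pytest

from burstlab.simulate import simulate_property
from burstlab.types import SpikeTrain


@pytest.fixture(scope="session")
def d7_trains():
    """100 regular-short-burst trains (300 s), the benchmark batch."""
    return [simulate_property("D7", i, seed=1) for i in range(100)]


@pytest.fixture(scope="session")
def d11_trains():
    """100 noisy bursting trains (300 s)."""
    return [simulate_property("D11", i, seed=1) for i in range(100)]


@pytest.fixture
def sparse_train_with_cluster():
    """A 0.1-Hz background with a dense 10-spike 10-ms-spacing cluster."""
    rng = np.random.default_rng(7)
    background = np.sort(rng.uniform(0, 300, 30))
    cluster = 150.0 + np.arange(10) * 0.01
    times = np.sort(np.concatenate([background, cluster]))
    assert np.all(np.diff(times) > 0)
    return SpikeTrain(times=times, duration=300.0, id="cluster"), cluster
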