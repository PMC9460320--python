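import numpy as np
import pytest

from swimforce import simulate as sim


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def geometry():
    return sim.default_geometry()


@pytest.fixture
def quiet_noise():
    """All noise sources off: streams reproduce the truth exactly."""
    return sim.NoiseSpec(gyro_sd=0.0, accel_sd=0.0, marker_sd=0.0, pressure_sd=0.0)


@pytest.fixture(scope="session")
def default_stroke():
    return sim.simulate_stroke()


def random_unit_quaternions(n, seed=0):
    rng = np.random.default_rng(seed)
    q = rng.normal(size=(n, 4))
    return q / np.linalg.norm(q, axis=1, keepdims=True)
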