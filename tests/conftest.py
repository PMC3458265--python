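import numpy as np
import pytest

from geotrend.simulate import generate_units, preset


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def mixed_table():
    return generate_units(preset("mixed", seed=7))


@pytest.fixture(scope="session")
def env_only_table():
    return generate_units(preset("env_only", seed=7))


def exact_correlated_pair(r: float, n: int = 23, seed: int = 0):
    """Two vectors whose sample correlation is exactly ``r`` (orthonormal
    basis construction, independent of the statistic under test)."""
    g = np.random.default_rng(seed)
    a = g.standard_normal(n)
    b = g.standard_normal(n)
    a = a - a.mean()
    b = b - b.mean()
    b = b - (a @ b) / (a @ a) * a
    a = a / np.linalg.norm(a)
    b = b / np.linalg.norm(b)
    return a, r * a + np.sqrt(1.0 - r * r) * b
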