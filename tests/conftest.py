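import numpy as np
import pytest

from skinperm import Environment, PermeantSpec, SpatialProfile


@pytest.fixture
def env():
    """Study conditions: 305.15 K, 30-layer barrier."""
    return Environment()


@pytest.fixture
def env1():
    """Single-layer environment for oracle/integral comparisons."""
    return Environment(n_layers=1)


@pytest.fixture
def acid():
    return PermeantSpec(name="hx", pka=4.5, acid_class="acid")


@pytest.fixture
def base():
    return PermeantSpec(name="bx", pka=8.5, acid_class="base")


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def make_profile(z, value, **kw):
    return SpatialProfile(z=np.asarray(z, float), value=np.asarray(value, float), **kw)


@pytest.fixture
def flat_profiles():
    """Flat PMF (G=0) and constant diffusion over [0, 10.4] nm."""
    z = np.arange(0.0, 10.4 + 1e-9, 0.01)
    g = SpatialProfile(z=z, value=np.zeros_like(z), label="pmf")
    d = SpatialProfile(z=z, value=np.full_like(z, 0.05), label="diffusion")
    return g, d


def random_smooth_profiles(rng, z=None, max_barrier=15.0):
    """Random sum-of-Gaussians PMF (min 0) and smooth positive D."""
    if z is None:
        z = np.arange(0.0, 5.2 + 1e-9, 0.01)
    g = np.zeros_like(z)
    for _ in range(4):
        amp = rng.uniform(-10, max_barrier)
        c = rng.uniform(0.5, z[-1] - 0.5)
        w = rng.uniform(0.3, 1.0)
        g += amp * np.exp(-((z - c) ** 2) / (2 * w**2))
    g -= g.min()
    d = 0.05 * (1.0 + 0.5 * np.sin(2 * np.pi * z / z[-1] + rng.uniform(0, 6)))
    return (
        SpatialProfile(z=z, value=g, label="pmf"),
        SpatialProfile(z=z, value=d, label="diffusion"),
    )
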