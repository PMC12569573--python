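import numpy as np
import pytest

from lvnckit.phantoms import PhantomSpec, generate_slice


@pytest.fixture(scope="session")
def default_slice():
    """One deterministic normal phantom at the default 128 px geometry."""
    return generate_slice(PhantomSpec(seed=7))


@pytest.fixture(scope="session")
def small_slice():
    """A 64 px phantom slice for cheap geometry/ROI tests."""
    spec = PhantomSpec(
        image_size=64,
        cavity_radius=14.0,
        wall_thickness=5.0,
        trabecular_fraction=0.3,
        seed=11,
    )
    return generate_slice(spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
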