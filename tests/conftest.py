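import numpy as np
import pytest

from nmgreg import Image2D, PhantomConfig, Volume3D, make_vessel_phantom


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def random_image(rng):
    return Image2D(pixels=rng.random((12, 10)), spacing=(1.0, 1.0))


@pytest.fixture
def small_volume(rng):
    return Volume3D(voxels=rng.random((8, 8, 8)), spacing=(1.0, 1.0, 1.0))


@pytest.fixture(scope="session")
def vessel_volume():
    """One 64-voxel vessel phantom shared across tests (deterministic)."""
    return make_vessel_phantom(PhantomConfig(size=64, seed=42))
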