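import numpy as np
import pytest

from tractgex.core_volumes import Volume, volume_from_spacing
from tractgex.synthetic_data import PhantomSpec


@pytest.fixture(scope="session")
def small_phantom() -> PhantomSpec:
    """A coarse phantom shared by slower tests (32^3 at 0.25 mm)."""
    return PhantomSpec(grid_shape=(32, 32, 32), spacing=0.25, rng_seed=7)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


@pytest.fixture()
def random_volume(rng) -> Volume:
    return volume_from_spacing(rng.random((8, 8, 8)).astype(np.float32), 0.5)


def smooth_linear_volume(shape=(24, 24, 24), spacing=0.25) -> Volume:
    """A trilinear-exact (affine in space) intensity ramp for resampling oracles."""
    idx = np.indices(shape).astype(float)
    data = 0.2 + 0.01 * idx[0] + 0.02 * idx[1] - 0.005 * idx[2]
    return volume_from_spacing(data, spacing)
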