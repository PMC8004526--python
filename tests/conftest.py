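import numpy as np
import pytest

from patchreg.deform import DisplacementField
from patchreg.volumes_io import Volume3D


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def ramp_volume():
    """Intensity equals the x index; handy for closed-form shift checks."""
    z, y, x = np.indices((12, 12, 12), dtype=np.float64)
    return Volume3D(data=x)


@pytest.fixture
def random_volume(rng):
    return Volume3D(data=rng.random((16, 16, 16)))


def smooth_random_field(shape, magnitude, seed=0, smoothness=4.0):
    from scipy import ndimage

    gen = np.random.default_rng(seed)
    vec = np.empty(tuple(shape) + (3,))
    for c in range(3):
        vec[..., c] = ndimage.gaussian_filter(gen.standard_normal(shape), smoothness)
    peak = np.sqrt((vec ** 2).sum(-1)).max()
    return DisplacementField(vectors=vec * magnitude / max(peak, 1e-12))


@pytest.fixture
def smooth_field():
    return smooth_random_field((16, 16, 16), magnitude=2.0, seed=3)
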