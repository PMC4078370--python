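import numpy as np
import pytest

from petbtv.grid import BinaryMask, ImageVolume
from petbtv.phantom import PhantomSpec, generate_phantom_pair


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def clean_spec():
    """Noise- and blur-free phantom conditions: exact geometric ground truth."""
    return PhantomSpec(noise_sd=0.0, psf_fwhm=0.0)


@pytest.fixture
def clean_pair(clean_spec):
    return generate_phantom_pair(clean_spec)


def make_volume(data, spacing=(2.0, 2.0, 2.0)):
    return ImageVolume(np.asarray(data, dtype=float), spacing)


def make_mask(data, spacing=(2.0, 2.0, 2.0)):
    return BinaryMask(np.asarray(data, dtype=bool), spacing)


def ellipsoid_mask(shape, spacing, center, radii):
    vol = ImageVolume(np.zeros(shape), spacing)
    gx, gy, gz = vol.coord_grids()
    q = (
        ((gx - center[0]) / radii[0]) ** 2
        + ((gy - center[1]) / radii[1]) ** 2
        + ((gz - center[2]) / radii[2]) ** 2
    )
    return BinaryMask(q <= 1.0, spacing)
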