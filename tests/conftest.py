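import dataclasses

import numpy as np
import pytest

from cbctreg import PhantomSpec, generate_pair
from cbctreg.transform import RigidTransform
from cbctreg.volgrid import BinaryMask, ImageVolume, Modality


def make_volume(shape=(16, 16, 8), spacing=(1.0, 1.0, 1.0), origin=(0.0, 0.0, 0.0),
                seed=0, modality=Modality.CT, smooth=False):
    rng = np.random.default_rng(seed)
    v = rng.normal(0.0, 100.0, size=shape)
    if smooth:
        from scipy.ndimage import gaussian_filter

        v = gaussian_filter(v, 2.0)
    return ImageVolume(v, spacing, origin, modality)


def make_sphere_mask(shape=(24, 24, 24), spacing=(1.0, 1.0, 1.0), center=None,
                     radius=6.0, origin=(0.0, 0.0, 0.0)):
    g = np.indices(shape).transpose(1, 2, 3, 0) * np.asarray(spacing) + np.asarray(origin)
    if center is None:
        center = np.asarray(origin) + (np.asarray(shape) - 1) / 2.0 * np.asarray(spacing)
    d = np.sqrt(np.sum((g - np.asarray(center)) ** 2, axis=-1))
    return BinaryMask((d <= radius).astype(np.uint8), spacing, origin)


@pytest.fixture(scope="session")
def coarse_clean_pair():
    """Reduced-resolution pair, zero motion, no gas."""
    return generate_pair(dataclasses.replace(PhantomSpec().coarse(), seed=3))


@pytest.fixture(scope="session")
def coarse_moving_pair():
    """Reduced-resolution pair with setup error, prostate offset and gas."""
    spec = dataclasses.replace(
        PhantomSpec().coarse(),
        setup_transform=RigidTransform(rotations=(0.01, -0.015, 0.02), translations=(3.0, -2.0, 2.0)),
        prostate_offset=(2.0, -3.0, 1.0),
        gas_fraction=0.4, gas_fraction_ct=0.32, distension_factor=1.2,
        seed=11,
    )
    return generate_pair(spec)


@pytest.fixture(scope="session")
def default_pair():
    """One pair at the full study resolution (1x1x3 mm CT, 1 mm CBCT)."""
    spec = PhantomSpec(
        setup_transform=RigidTransform(rotations=(0.02, -0.03, 0.025), translations=(5.0, -4.0, 3.0)),
        prostate_offset=(4.0, -3.0, 0.0),
        seed=7,
    )
    return generate_pair(spec)
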