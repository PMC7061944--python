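import numpy as np
import pytest
from scipy import ndimage as ndi

from scaffoldchar import BinaryVolume


VOX = 3.0  # µm, close to the 2.97 µm of typical scaffold micro-CT scans


@pytest.fixture(scope="session")
def channel_45():
    """45 µm straight channel along z in a 64³ grid at 3 µm voxels."""
    from scaffoldchar import generate_channel_fixture
    return generate_channel_fixture((64, 64, 64), VOX, 45.0, axis="z")


@pytest.fixture(scope="session")
def lattice_60_27():
    """60 µm pores / 27 µm windows sphere lattice, 80³ at 3 µm voxels."""
    from scaffoldchar import generate_sphere_lattice
    return generate_sphere_lattice((80, 80, 80), VOX, 60.0, 27.0)


def random_blob_mask(seed: int, shape=(40, 40, 40), voxel_size=VOX,
                     threshold=0.0) -> BinaryVolume:
    """Smoothed-noise random mask: connected blobby pore phase."""
    rng = np.random.default_rng(seed)
    field = ndi.gaussian_filter(rng.normal(size=shape), sigma=4.0)
    mask = field > np.quantile(field, 0.35 + threshold)
    # Guarantee both phases and pore contact with the z- inlet face.
    if not mask[0].any():
        mask[0, shape[1] // 2, shape[2] // 2] = True
    return BinaryVolume(mask=mask, voxel_size=voxel_size)
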