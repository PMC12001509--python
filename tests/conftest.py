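import numpy as np
import pytest

from perimem.imaging_io import ImageChannel
from perimem.scene_synth import SceneSpec


@pytest.fixture
def noisefree_spec():
    """Small deterministic scene with exact painted intensities."""
    return SceneSpec(
        image_height_px=384,
        image_width_px=384,
        n_cells=5,
        gaussian_noise_sd=0.0,
        poisson_noise=False,
        seed=11,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def make_channel(pixels, role, bit_depth=16, pixel_size_um=0.082):
    return ImageChannel(
        pixels=np.asarray(pixels),
        bit_depth=bit_depth,
        pixel_size_um=pixel_size_um,
        role=role,
    )


@pytest.fixture
def disk_image():
    """A 3000-count disk of radius 20 centred in a 128x128 field."""
    rows, cols = np.mgrid[0:128, 0:128]
    disk = np.hypot(rows - 64, cols - 64) <= 20
    return (disk * 3000).astype(np.uint16)
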