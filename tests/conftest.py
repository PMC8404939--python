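import numpy as np
import pytest

from gaseg.phantom import PhantomConfig, generate_phantom


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_phantom():
    """One 64x64 phantom with a clear bright lesion and its mask."""
    cfg = PhantomConfig(image_size=64, n_lesions=1, lesion_contrast=0.5,
                        vessel_count=2, seed=3)
    return generate_phantom(cfg)


@pytest.fixture(scope="session")
def disk_image():
    """Noiseless bright disk on a dark background plus its true mask."""
    yy, xx = np.mgrid[0:96, 0:96]
    mask = ((yy - 48) ** 2 + (xx - 48) ** 2) <= 28 ** 2
    img = np.where(mask, 0.8, 0.2)
    return img, mask.astype(np.uint8)
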