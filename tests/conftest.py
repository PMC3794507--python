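import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def two_patch_image():
    """Flat dark patch (30) beside a flat light patch (220)."""
    img = np.empty((8, 8), dtype=np.uint8)
    img[:, :4] = 220
    img[:, 4:] = 30
    return img


@pytest.fixture
def small_gel():
    from gelseg.synthgel import SyntheticGelSpec, generate_gel

    spec = SyntheticGelSpec(height=64, width=64, n_spots=5, n_ghost=0,
                            sigma_spot=(2.0, 3.0), noise_sd=10.0, seed=7)
    img, mask, catalog = generate_gel(spec)
    return spec, img, mask, catalog
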