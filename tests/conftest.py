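import numpy as np
import pytest
from scipy import ndimage


@pytest.fixture(scope="session")
def smooth_image():
    """Smooth 128x128 test pattern with rich gradients, values in [0, 1]."""
    rng = np.random.default_rng(42)
    img = ndimage.gaussian_filter(rng.normal(size=(128, 128)), sigma=5.0)
    return (img - img.min()) / np.ptp(img)


@pytest.fixture(scope="session")
def small_image():
    rng = np.random.default_rng(7)
    img = ndimage.gaussian_filter(rng.normal(size=(64, 64)), sigma=4.0)
    return (img - img.min()) / np.ptp(img)
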