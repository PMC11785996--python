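import numpy as np
import pytest

from simqual import PhantomSpec, generate_phantom


@pytest.fixture(scope="session")
def phantom240():
    """Default 240×240 brain phantom (image, mask), seed 0."""
    return generate_phantom(PhantomSpec(seed=0))


@pytest.fixture(scope="session")
def phantom_image(phantom240):
    return phantom240[0]


@pytest.fixture(scope="session")
def sharp_phantom():
    """Nearly unsmoothed phantom: sharp edges for blur-metric dynamics."""
    img, _ = generate_phantom(PhantomSpec(seed=0, smoothing=0.3, noise_level=0.01))
    return img


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
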