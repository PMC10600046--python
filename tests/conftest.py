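import numpy as np
import pytest

from xshuffle import make_class_image, make_toy_image


@pytest.fixture
def toy4():
    """4x4 toy image with 16 pairwise-distinct pixel triplets."""
    return make_toy_image(4, 4)


@pytest.fixture
def toy2():
    """2x2 toy image with 4 distinct triplets."""
    return make_toy_image(2, 2)


@pytest.fixture(scope="session")
def class_image_320():
    """One 320x320 naturalistic fixture image (divisible by all block sizes)."""
    img, _ = make_class_image(0, 320, 320, rng=np.random.default_rng(7))
    return img


@pytest.fixture(scope="session")
def class_images_160():
    """A bank of small class images for stimulus-set builds."""
    rng = np.random.default_rng(11)
    images = []
    for i in range(40):
        img, label = make_class_image(i % 10, 160, 160, rng)
        images.append((img, label))
    return images
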