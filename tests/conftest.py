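import numpy as np
import pytest

from tensionmap import synthetic as syn
from tensionmap.types import SceneSpec


@pytest.fixture(scope="session")
def circle_spec():
    return SceneSpec(shape="circle", R0=12.5, pixel_size=0.1,
                     image_size=(300, 300), seed=0)


@pytest.fixture(scope="session")
def circle_masks(circle_spec):
    return syn.make_mask(circle_spec)


@pytest.fixture(scope="session")
def small_circle_masks():
    """Smaller scene for the heavier image-processing tests."""
    return syn.make_mask(SceneSpec(shape="circle", R0=10.0, pixel_size=0.1,
                                   image_size=(256, 256), seed=0))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
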