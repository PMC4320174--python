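import numpy as np
import pytest

from uie.synthetic_fixtures import SceneSpec, make_pair

DEFAULT_SUITE_BASE_SEED = 7
DEFAULT_SUITE_SIZE = 20


@pytest.fixture(scope="session")
def scene_suite():
    """The default 20-scene clean/degraded fixture suite (seeds 7..26)."""
    return [
        make_pair(SceneSpec(seed=DEFAULT_SUITE_BASE_SEED + i))
        for i in range(DEFAULT_SUITE_SIZE)
    ]


@pytest.fixture(scope="session")
def scene_pair(scene_suite):
    """One representative (clean, degraded) pair."""
    return scene_suite[0]


@pytest.fixture
def rng():
    return np.random.default_rng(20260925)


@pytest.fixture
def random_image(rng):
    """A 12x9 random 8-bit RGB image as float64."""
    return rng.integers(0, 256, size=(12, 9, 3)).astype(np.float64)
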