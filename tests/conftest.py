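import numpy as np
import pytest

from tractdissect import synthetic


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def default_scene():
    """The default motorMFB phantom scene (shared; treat as read-only)."""
    return synthetic.make_motor_mfb_scene(rng_seed=7)


@pytest.fixture(scope="session")
def scene_index():
    """Helper building identity-based index maps for selected subsets."""
    def _index(scene):
        return {id(s): i for i, s in enumerate(scene.tractogram.streamlines)}
    return _index
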