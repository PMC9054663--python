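import numpy as np
import pytest
from hypothesis import settings

from trinet import synthetic

settings.register_profile("suite", deadline=None, max_examples=25, derandomize=True)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def small_atlas():
    """4-region atlas on a 4x4x2 grid."""
    return synthetic.make_atlas(4, (4, 4, 2))


@pytest.fixture(scope="session")
def mini_dataset():
    """A small planted-state dataset: 4 runs x 120 frames, 6 states, SNR 1."""
    atlas, gt, runs = synthetic.default_state_dataset(
        seed=11, n_runs=4, n_frames=120, grid_shape=(6, 6, 3), n_regions=12)
    return atlas, gt, runs


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
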