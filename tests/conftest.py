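import warnings

import numpy as np
import pytest

from glomix.noise import WT
from glomix.synthetic import AtlasSpec, generate_atlas

warnings.filterwarnings("ignore", category=FutureWarning)


@pytest.fixture(scope="session")
def wt_atlas():
    """A small synthetic animal used across decoder/deconvolution tests."""
    return generate_atlas(AtlasSpec(n_rois=60, seed=7), animal_id="m1")


@pytest.fixture(scope="session")
def full_atlas():
    """Full-size (155 ROI) synthetic animal."""
    return generate_atlas(AtlasSpec(seed=11), animal_id="m2")


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def wt_noise():
    return WT
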