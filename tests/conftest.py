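import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the reference oracle module

from ionspike.morphology import generate_synthetic_morphology


@pytest.fixture(scope="session")
def ball_and_stick():
    return generate_synthetic_morphology("ball_and_stick", length=600.0,
                                         mean_segment_length=40.0)


@pytest.fixture(scope="session")
def binary_tree():
    return generate_synthetic_morphology("random_binary_tree", depth=5,
                                         mean_segment_length=40.0, rng_seed=3)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
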