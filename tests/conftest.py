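import logging

import numpy as np
import pytest

from cytodistill.data import split_dataset
from cytodistill.synth import SyntheticSpec, generate_dataset

logging.getLogger("cytodistill").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def small_dataset():
    """100-image, 32x32 synthetic dataset with a 3:1:1 split (60/20/20)."""
    spec = SyntheticSpec(image_size=32)
    ds = generate_dataset(spec, n_per_class=20, seed=7)
    return split_dataset(ds, seed=7)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
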