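import numpy as np
import pytest

import graftnet as gn


@pytest.fixture(scope="session")
def truth():
    """The default synthetic ground-truth model (seed 0)."""
    return gn.make_ground_truth(seed=0)


@pytest.fixture(scope="session")
def dataset(truth):
    """Noisy study-shaped dataset generated from the default truth."""
    return gn.generate_dataset(truth)


@pytest.fixture(scope="session")
def clean_dataset():
    """Noise-free dataset (tables equal the truth model's output exactly)."""
    return gn.generate_dataset(gn.make_ground_truth(seed=0, noise=0.0))


@pytest.fixture(scope="session")
def grid():
    return gn.TimeGrid()


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
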