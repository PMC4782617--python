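import numpy as np
import pytest

from texdirect import SyntheticConfig, generate_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def default_dataset():
    """The standard synthetic study conditions: 40 normal + 40 abnormal."""
    return generate_dataset(SyntheticConfig())


@pytest.fixture(scope="session")
def small_config():
    """A fast generator config for pipeline-level tests."""
    return SyntheticConfig(image_size=(64, 64), n_per_class=12,
                           background_smoothness=3.0, seed=3)
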