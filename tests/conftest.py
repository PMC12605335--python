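import numpy as np
import pytest

from lessnet.data import SyntheticConfig, generate_dataset, split_dataset


@pytest.fixture(scope="session")
def tiny_config():
    return SyntheticConfig(image_size=64, lesion_area_fraction_range=(0.02, 0.15),
                           seed=7)


@pytest.fixture(scope="session")
def tiny_dataset(tiny_config):
    return generate_dataset(24, tiny_config)


@pytest.fixture(scope="session")
def tiny_split(tiny_dataset):
    return split_dataset(tiny_dataset, test_fraction=0.25, label_ratio=0.5, seed=1)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
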