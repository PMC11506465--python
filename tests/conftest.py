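import numpy as np
import pytest

from enose import synthetic_data
from enose.gabp import GaConfig, NetworkSpec


@pytest.fixture(scope="session")
def small_dataset():
    """A reduced 28 degC storage experiment (600 sensor rows)."""
    config = synthetic_data.default_config(28, seed=3, n_rows=600)
    return synthetic_data.generate_dataset(config)


@pytest.fixture(scope="session")
def quality_table(small_dataset):
    return small_dataset[1]


@pytest.fixture(scope="session")
def blob_data():
    """Three well-separated 2-D Gaussian blobs with grade labels 1/2/3."""
    rng = np.random.default_rng(11)
    centers = np.array([[0.1, 0.1], [0.9, 0.1], [0.5, 0.9]])
    X = np.vstack([rng.normal(c, 0.02, size=(30, 2)) for c in centers])
    y = np.repeat([1, 2, 3], 30)
    return X, y


@pytest.fixture
def toy_spec():
    return NetworkSpec(n_input=2, n_hidden=5, n_output=3)


@pytest.fixture
def quick_ga():
    return GaConfig(population_size=16, generations=15, seed=5)
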