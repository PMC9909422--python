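import numpy as np
import pytest

from hirand.simulate import SimulationSpec, simulate_dataset


@pytest.fixture(scope="session")
def tiny_dataset():
    """Miniature simulated dataset (24 samples x 30 genes, 5 true predictors)."""
    return simulate_dataset(SimulationSpec(g=30, n=24, n_true=5, seed=11))


@pytest.fixture(scope="session")
def small_dataset():
    """The scaled-down benchmark dataset (120 samples x 200 genes, 10 true predictors)."""
    return simulate_dataset(SimulationSpec(g=200, n=120, n_true=10, seed=7))


@pytest.fixture
def rng():
    return np.random.default_rng(42)
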