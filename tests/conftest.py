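import numpy as np
import pytest

from nichetraj import NicheTrajectory, RunConfig, simulate_dataset


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_dataset():
    """300-cell benchmark instance (same structure, desk-scale)."""
    return simulate_dataset(n_cells=300, seed=7)


@pytest.fixture(scope="session")
def small_config():
    return RunConfig(k_neighbors=30, sigma_index=15, max_epochs=300, seed=7)


@pytest.fixture(scope="session")
def small_results(small_dataset, small_config):
    """A fitted run on the 300-cell instance, shared across tests."""
    model = NicheTrajectory.from_dataframe(small_dataset.cells, small_config)
    return model.fit()
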