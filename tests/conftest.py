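import numpy as np
import pandas as pd
import pytest

from statedecon.matrix import ExpressionMatrix
from statedecon.syndata import SyntheticConfig, simulate_bulk, simulate_states


@pytest.fixture(scope="session")
def small_config():
    return SyntheticConfig(
        n_states=4,
        n_genes=300,
        markers_per_state=25,
        n_cells_per_state=40,
        n_bulk_samples=30,
        marker_effect=4.0,
        noise_sd=0.4,
        dropout_rate=0.2,
        n_patients=3,
        batch_sd=0.3,
        seed=2,
    )


@pytest.fixture(scope="session")
def sc_data(small_config):
    return simulate_states(small_config)


@pytest.fixture(scope="session")
def bulk_data(sc_data):
    _, truth = sc_data
    return simulate_bulk(truth, 30, 0.1, seed=11)


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def toy_matrix():
    """5 genes x 4 observations with hand-checkable values."""
    values = pd.DataFrame(
        [
            [1.0, 2.0, 3.0, 4.0],
            [4.0, 3.0, 2.0, 1.0],
            [2.0, 2.0, 2.0, 2.0],
            [0.0, 5.0, 0.0, 5.0],
            [1.5, 1.5, 3.5, 0.5],
        ],
        index=[f"g{i}" for i in range(5)],
        columns=[f"c{i}" for i in range(4)],
    )
    return ExpressionMatrix(values)
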