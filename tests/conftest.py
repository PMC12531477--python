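import numpy as np
import pandas as pd
import pytest

from decoylink import RecordTable, SimulationConfig, simulate_files


@pytest.fixture(scope="session")
def toy_problem():
    """A small simulated linkage problem with known truth."""
    config = SimulationConfig(
        n_a=200, n_b=500, overlap=0.5, target_discrimination=0.9, seed=7
    )
    A, B, truth = simulate_files(config)
    return A, B, truth


@pytest.fixture()
def two_column_table():
    """Perfectly correlated two-column table: X determines Y."""
    df = pd.DataFrame({"X": ["a", "a", "b", "b"], "Y": [0, 0, 1, 1]})
    return RecordTable(df, ["X", "Y"])


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
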