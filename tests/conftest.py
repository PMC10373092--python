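import numpy as np
import pandas as pd
import pytest

import uegkit as uk


def make_matrix(values, unit="counts", genes=None, samples=None):
    arr = np.asarray(values, dtype=float)
    genes = genes or [f"g{i}" for i in range(arr.shape[0])]
    samples = samples or [f"s{j}" for j in range(arr.shape[1])]
    return uk.ExpressionMatrix(pd.DataFrame(arr, index=genes, columns=samples), unit)


@pytest.fixture(scope="session")
def demo_run():
    """One full pipeline run on the demo compendium, shared across tests."""
    return uk.run_pipeline({"input": {"preset": "demo"}, "seed": 1})


@pytest.fixture(scope="session")
def candidate_run():
    """One full pipeline run on the bundled candidate-evaluation scenario."""
    return uk.run_pipeline({"input": {"preset": "candidates"}, "seed": 3})


@pytest.fixture()
def small_counts():
    return make_matrix([[10, 0, 5], [30, 0, 5], [0, 0, 5]])


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)
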