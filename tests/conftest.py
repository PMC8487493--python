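import warnings

import numpy as np
import pandas as pd
import pytest

import neurodiverge as nd

warnings.filterwarnings("ignore", category=UserWarning)


@pytest.fixture(scope="session")
def default_dataset():
    """One default-world synthetic dataset shared across tests."""
    return nd.simulate_all(nd.SimulationConfig(seed=0))


@pytest.fixture(scope="session")
def normalized(default_dataset):
    kept, norm = nd.normalize(default_dataset.counts)
    return kept, norm


@pytest.fixture(scope="session")
def de_results(default_dataset, normalized):
    kept, norm = normalized
    return nd.run_comparisons(kept, default_dataset.samples, norm=norm)


@pytest.fixture()
def small_counts():
    """Deterministic 100-gene, 4-sample count matrix."""
    rng = np.random.default_rng(123)
    counts = rng.poisson(rng.lognormal(3, 1.5, size=(100, 1)), size=(100, 4))
    df = pd.DataFrame(counts, index=[f"g{i:03d}" for i in range(100)],
                      columns=["a", "b", "c", "d"])
    return nd.CountMatrix(df)


@pytest.fixture(scope="session")
def four_group_samples():
    rows = []
    for tag, geo, sex, k in [("AF", "allopatric", "female", 3),
                             ("AM", "allopatric", "male", 3),
                             ("SF", "sympatric", "female", 3),
                             ("SM", "sympatric", "male", 3)]:
        rows += [(f"{tag}{i}", geo, sex) for i in range(k)]
    df = pd.DataFrame(rows, columns=["sample_id", "geography", "sex"])
    return nd.SampleTable(df.set_index("sample_id"))
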