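import numpy as np
import pandas as pd
import pytest

from dysbiome import AbundanceTable, SimulationConfig, simulate_all


@pytest.fixture(scope="session")
def small_config():
    return SimulationConfig(
        n_cases=40, n_controls=50, n_features=60, n_enriched=8, n_depleted=4,
        n_gene_families=150, n_diff_gene_families=90, seed=11,
    )


@pytest.fixture(scope="session")
def small_bundle(small_config):
    return simulate_all(small_config)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def make_table(values, sample_ids=None, feature_ids=None, relative=True):
    values = np.asarray(values, dtype=float)
    n, m = values.shape
    sample_ids = sample_ids or [f"s{i}" for i in range(n)]
    feature_ids = feature_ids or [f"f{j}" for j in range(m)]
    return AbundanceTable(
        pd.DataFrame(values, index=sample_ids, columns=feature_ids),
        relative=relative,
    )


@pytest.fixture()
def table_factory():
    return make_table
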