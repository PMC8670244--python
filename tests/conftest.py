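import numpy as np
import pandas as pd
import pytest

import ferrostrat as fs


@pytest.fixture(scope="session")
def cohort():
    """Default synthetic cohort, seed 1, shared across tests."""
    return fs.simulate_cohort(fs.CohortConfig(seed=1))


@pytest.fixture(scope="session")
def ferrdb():
    return fs.read_gene_sets(fs.bundled_path("ferrdb_roles.synthetic_subset.gmt"))


@pytest.fixture()
def small_expr():
    """3-gene x 4-sample FPKM matrix with known values."""
    return pd.DataFrame(
        [[10.0, 0.0, 5.0, 2.5], [100.0, 100.0, 100.0, 100.0], [1.0, 2.0, 3.0, 4.0]],
        index=["GENEA", "GENEB", "GENEC"],
        columns=["S1", "S2", "S3", "S4"],
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
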