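import numpy as np
import pytest

from sargasso import simulate
from sargasso.table import OtuTable


@pytest.fixture(scope="session")
def small_pool():
    return simulate.generate_source_pool(40, 1.5, seed=42)


@pytest.fixture()
def toy_table():
    counts = [[5, 3, 2, 0], [0, 2, 8, 0], [1, 1, 1, 12]]
    return OtuTable(counts, ["s1", "s2", "s3"], ["o1", "o2", "o3", "o4"])


@pytest.fixture(scope="session")
def transect_dataset():
    """Neutral 16-sample transect reused by the slower integration tests."""
    pool = simulate.generate_source_pool(120, 1.8, seed=7)
    cfg = simulate.SimConfig(n_stations=8, reads_per_sample=2500, seed=7)
    return simulate.simulate_dataset(cfg, pool)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20180421)
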