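import numpy as np
import pytest

from tadshift.hic_io import BinInterval, ContactMatrix
from tadshift.simulator import SimulationConfig, simulate_matrix, simulate_pair


@pytest.fixture(scope="session")
def five_tad_matrix():
    """Five 100-bin TADs at intensity 3: the standard recovery fixture."""
    layout = [BinInterval(i * 100, (i + 1) * 100) for i in range(5)]
    cfg = SimulationConfig(
        n_tads=5, size_min=100, size_max=100, n_merges=0,
        mu_min=3, mu_max=3, seed=7,
    )
    m = simulate_matrix(layout, cfg, np.random.default_rng(7))
    return m, layout


@pytest.fixture(scope="session")
def small_pair():
    """A small two-condition pair with one merge, for pipeline smoke tests."""
    cfg = SimulationConfig(
        n_tads=4, size_min=60, size_max=90, n_merges=1,
        mu_min=3, mu_max=3, seed=42,
    )
    m1, m2, truth = simulate_pair(cfg)
    return m1, m2, truth


@pytest.fixture()
def step_row_matrix():
    """Noise-free matrix whose rows carry a clean plateau on bins 40-60."""
    n = 101
    row = np.ones(n)
    row[40:61] = 5.0
    return ContactMatrix(np.tile(row, (n, 1)))
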