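import numpy as np
import pytest

from tftarget.synthetic import SyntheticConfig, generate_benchmark


@pytest.fixture(scope="session")
def small_benchmark():
    """A small two-condition benchmark shared by read-only tests."""
    cfg = SyntheticConfig(n_genes=40, n_train=12, grid_size=40)
    return generate_benchmark(cfg, seed=11)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
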