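import numpy as np
import pytest

from misint.pipeline import screen_benchmark
from misint.synthetic_data import GeneratorConfig, make_benchmark, make_dimer


@pytest.fixture(scope="session")
def config() -> GeneratorConfig:
    return GeneratorConfig(seed=11)


@pytest.fixture(scope="session")
def benchmark(config):
    """The main planted-precedent benchmark shared across the suite."""
    return make_benchmark(n_templates=8, n_pos_pairs=16, n_neg_pairs=20, config=config)


@pytest.fixture(scope="session")
def screen(benchmark):
    """Full (pair x template) screen of the shared benchmark."""
    return screen_benchmark(benchmark)


@pytest.fixture(scope="session")
def small_dimer(config):
    return make_dimer(40, 45, config, seed=2, dimer_id="TDIM")


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
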