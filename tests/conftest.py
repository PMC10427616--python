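import numpy as np
import pytest

from tmcontact import synthdata
from tmcontact.nn import layers as nn_layers


@pytest.fixture(scope="session")
def toy_c3():
    """C3-symmetric TMP-like helical bundle."""
    return synthdata.make_toy_complex(3, 48, seed=5, regime="tmp")


@pytest.fixture(scope="session")
def toy_dimer():
    return synthdata.make_toy_complex(2, 48, seed=3, regime="soluble")


@pytest.fixture(scope="session")
def small_bench_cfg():
    return synthdata.BenchmarkConfig(
        n_soluble_train=2, n_soluble_valid=1,
        n_tmp_train=2, n_tmp_valid=1, n_tmp_test=2)


@pytest.fixture(scope="session")
def tiny_target(small_bench_cfg):
    """One fully featurised TMP-like target."""
    return synthdata.build_target("tmp", 7, small_bench_cfg)


@pytest.fixture
def float64_params():
    """Run network modules in float64 for tight oracle comparisons."""
    old = nn_layers.DTYPE
    nn_layers.DTYPE = np.float64
    yield
    nn_layers.DTYPE = old
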