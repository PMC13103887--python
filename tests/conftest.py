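import numpy as np
import pytest

from datediag import simulate_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def strict_dataset():
    """One 100-tip strict-clock dataset (mu=10, tips 2010-2020, Ne=1)."""
    return simulate_dataset("constant", np.random.default_rng(20), n=100)


@pytest.fixture(scope="session")
def relaxed_dataset():
    """One 100-tip additive-relaxed-clock dataset (mu=10, omega=5)."""
    return simulate_dataset("relaxed", np.random.default_rng(21), n=100)


@pytest.fixture(scope="session")
def outlier_dataset():
    """Strict-clock dataset with 20 extra substitutions on 5 random tips."""
    return simulate_dataset("outliers", np.random.default_rng(22), n=100)
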