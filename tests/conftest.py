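import numpy as np
import pytest

from equipopk.io import load_table1


@pytest.fixture(scope="session")
def table1():
    """Bundled population estimates: (PKParameters, OmegaSpec, ResidualSpec)."""
    return load_table1()


@pytest.fixture(scope="session")
def table1_correlated():
    return load_table1(with_correlation=True)


@pytest.fixture
def rng():
    return np.random.default_rng(20240707)
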