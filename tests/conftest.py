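import numpy as np
import pytest

from beliefmodels import harness


@pytest.fixture(scope="session")
def cpm_fixture():
    """Small deterministic CPM-generated dataset with known truths."""
    return harness.make_fixture("cpm-switching-easy", seed=5, T=50)


@pytest.fixture(scope="session")
def hgf_fixture():
    """Small deterministic HGF-generated dataset with known truths."""
    return harness.make_fixture("hgf-diffusive-easy", seed=5, T=50)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
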