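import numpy as np
import pytest

from acns import NetworkSpec, PhantomConfig, make_dataset, parse_spec_string


@pytest.fixture(scope="session")
def selected_spec() -> NetworkSpec:
    """The selected network: ACNS(16,8,5,9,5,4) at scale factor 2."""
    return parse_spec_string("ACNS(16,8,5,9,5,4)", scale=2)


@pytest.fixture(scope="session")
def tiny_spec() -> NetworkSpec:
    """A <200-weight network for gradient and convergence checks."""
    return NetworkSpec(n_feature=2, n_map=2, w1=3, w_out=3, p=1, n=1, scale=2)


@pytest.fixture(scope="session")
def phantom_slices() -> list:
    """A small phantom dataset shared across tests (96x96, 6 slices)."""
    return make_dataset(PhantomConfig(size=96, seed=7), 6, role="train")


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
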