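import numpy as np
import pytest

from mitocomp.synthetic_data import SyntheticSpec, make_mitogenome


@pytest.fixture(scope="session")
def synthetic_record():
    """One deterministic synthetic mitogenome in the ancestral gene order."""
    return make_mitogenome(SyntheticSpec(seed=11, n_rearrangements=0), 0)


@pytest.fixture(scope="session")
def rearranged_record():
    """One deterministic synthetic mitogenome with tRNA-block rearrangements."""
    return make_mitogenome(SyntheticSpec(seed=11, n_rearrangements=3), 1)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
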