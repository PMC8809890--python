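import numpy as np
import pytest

import fomotor as fm


@pytest.fixture(scope="session")
def wt_model():
    return fm.build_model()


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260920)


def random_state(rng) -> fm.ProtonState:
    return fm.ProtonState(rng.integers(0, 2, size=12))
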