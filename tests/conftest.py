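import numpy as np
import pytest

from igtlab.task import build_standard_schedule


@pytest.fixture
def schedule():
    return build_standard_schedule(100, seed=7)


@pytest.fixture
def canonical_schedule():
    return build_standard_schedule(100, seed=0, loss_policy="fixed_canonical")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
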