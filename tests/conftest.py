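import numpy as np
import pytest

from sanstretch.sim import DemoPacemakerModel
from sanstretch.synthetic import APShapeParams, gen_ap_train


@pytest.fixture(scope="session")
def demo_model():
    return DemoPacemakerModel()


@pytest.fixture(scope="session")
def ap_train():
    """Default synthetic AP train plus its ground-truth table."""
    params = APShapeParams(n_cycles=10, dt=0.1, seed=1)
    trace, truth = gen_ap_train(params)
    return params, trace, truth


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
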