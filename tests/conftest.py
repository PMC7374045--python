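import numpy as np
import pytest

from tmesim.boolnet import parse_rules
from tmesim.demo import demo_model


@pytest.fixture(scope="session")
def demo():
    return demo_model()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def abc_net():
    """Tiny 3-node network used across modules."""
    return parse_rules(
        "targets, factors\n"
        "A, B & !C\n"
        "B, A | C\n"
        "C, !C\n",
        name="abc",
    )
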