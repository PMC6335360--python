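import numpy as np
import pytest

from omvsim import SaccadeModel, make_fixture


@pytest.fixture(scope="session")
def tiny():
    """Fast 10-unit, 2 ms configuration with its random structure."""
    return make_fixture("tiny", seed=7)


@pytest.fixture(scope="session")
def tiny_config(tiny):
    return tiny[0]


@pytest.fixture(scope="session")
def tiny_weights(tiny):
    return tiny[1]


@pytest.fixture(scope="session")
def trained_fit():
    """One full adaptation run at the reference settings (shared; slow)."""
    model = SaccadeModel.from_config(seed=1234)
    return model.fit(seed=1234)
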