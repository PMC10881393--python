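import numpy as np
import pytest

from cxsteer.steering_model import DEFAULT_FIT, build_population


@pytest.fixture(scope="session")
def pop():
    """The intact default 24-cell population with the fitted parameters."""
    return build_population()


@pytest.fixture(scope="session")
def fit():
    return DEFAULT_FIT


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
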