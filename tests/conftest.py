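import numpy as np
import pytest

from ammistab import AMMI, load_spring_barley


@pytest.fixture(scope="session")
def barley():
    """The bundled 32 x 6 spring-barley 1000-kernel-weight trial."""
    return load_spring_barley()


@pytest.fixture(scope="session")
def barley_ge(barley):
    return barley[0]


@pytest.fixture(scope="session")
def barley_meta(barley):
    return barley[1]


@pytest.fixture(scope="session")
def barley_model(barley_ge):
    return AMMI().fit(barley_ge)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
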