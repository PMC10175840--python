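import numpy as np
import pytest

from nemoresponse.protocol import make_protocol


@pytest.fixture(scope="session")
def behavior_protocol():
    """20 s air, 60 s CO2, 40 s air at 5 fps."""
    return make_protocol(20, 60, 40, 5, "CO2")


@pytest.fixture(scope="session")
def behavior_air_protocol():
    return make_protocol(20, 60, 40, 5, "air")


@pytest.fixture(scope="session")
def imaging_protocol():
    """Same timing at 2 fps with the imaging gas mix."""
    return make_protocol(20, 60, 40, 2, "CO2", pulse_composition="15% CO2")


@pytest.fixture(scope="session")
def imaging_air_protocol():
    return make_protocol(20, 60, 40, 2, "air")


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
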