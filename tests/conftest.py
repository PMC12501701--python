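import warnings

import pytest

from mpfpsl import (
    PulseTrainParams,
    RfPair,
    RfSetting,
    free_water_preset,
    liver_preset,
)


@pytest.fixture(scope="session")
def liver():
    return liver_preset()


@pytest.fixture(scope="session")
def free_water():
    return free_water_preset()


@pytest.fixture(scope="session")
def pair_fig4():
    """RF pair of the figure-level validation protocol (100/1000, 450/4500 Hz)."""
    return RfPair.from_hz(100.0, 1000.0, 450.0, 4500.0)


@pytest.fixture(scope="session")
def pair_study1():
    """RF pair of the sensitivity study (80/800, 350/3500 Hz)."""
    return RfPair.from_hz(80.0, 800.0, 350.0, 3500.0)


@pytest.fixture(scope="session")
def train10():
    """Reference pulsed protocol: Tp=10 ms, Tf=50 ms, n=10 (TSL=100 ms)."""
    return PulseTrainParams.from_ms(10.0, 50.0, 10)


@pytest.fixture(scope="session")
def rf_lo():
    return RfSetting.from_hz(80.0, 800.0)


@pytest.fixture(scope="session")
def rf_hi():
    return RfSetting.from_hz(350.0, 3500.0)


@pytest.fixture(autouse=True)
def _no_ratio_warnings():
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        yield
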