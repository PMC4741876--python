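import pytest

from ploidysim import load_default_calibration, load_default_rates


@pytest.fixture(scope="session")
def default_cal():
    return load_default_calibration()


@pytest.fixture(scope="session")
def default_rates():
    return load_default_rates()
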