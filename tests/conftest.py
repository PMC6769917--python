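import pytest

from facprof import REFERENCE_CALIBRATIONS, make_archetype_panel


@pytest.fixture(scope="session")
def panel():
    return make_archetype_panel(seed=0)


@pytest.fixture(scope="session")
def ppl2a_cal():
    return REFERENCE_CALIBRATIONS["PPL2A"]


@pytest.fixture(scope="session")
def ppl3s_cal():
    return REFERENCE_CALIBRATIONS["PPL3s"]


@pytest.fixture(scope="session")
def ppl4_cal():
    return REFERENCE_CALIBRATIONS["PPL4"]
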