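import pytest

from panelval.toy import DILUTION_AMPLICONS, dilution_panel, toy_panel


@pytest.fixture(scope="session")
def panel():
    return toy_panel()


@pytest.fixture(scope="session")
def cnv_panel():
    return dilution_panel()


@pytest.fixture(scope="session")
def amplicons():
    return DILUTION_AMPLICONS
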