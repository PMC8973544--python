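import pytest

from ttcrisk import load_catalogue, load_reference_panel, load_reference_survey


@pytest.fixture(scope="session")
def catalogue():
    return load_catalogue()


@pytest.fixture(scope="session")
def panel():
    return load_reference_panel()


@pytest.fixture(scope="session")
def reference_survey():
    return load_reference_survey()
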