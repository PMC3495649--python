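import pytest

from haplogeo import load_study_fixture, fixture_alignment


@pytest.fixture(scope="session")
def cp_dataset():
    return load_study_fixture("rpl32-trnL")


@pytest.fixture(scope="session")
def pal_dataset():
    return load_study_fixture("PAL")


@pytest.fixture(scope="session")
def cp_reconstruction():
    return fixture_alignment("rpl32-trnL")


@pytest.fixture(scope="session")
def pal_reconstruction():
    return fixture_alignment("PAL")
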