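import pytest

from cnvscreen import HmmModel, decoy_calls, fixture_tracks, table2_fixture


@pytest.fixture(scope="session")
def model():
    return HmmModel()


@pytest.fixture(scope="session")
def fixture():
    return table2_fixture()


@pytest.fixture(scope="session")
def bundle():
    return fixture_tracks()


@pytest.fixture(scope="session")
def decoys():
    return decoy_calls()
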