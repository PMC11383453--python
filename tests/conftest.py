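import pytest

from markovcea import reference_scenario


@pytest.fixture(scope="session")
def ref_scenario():
    return reference_scenario()


@pytest.fixture(scope="session")
def ref_result(ref_scenario):
    return ref_scenario.run()
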