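import pytest

from bdchain.presets import preset


@pytest.fixture(scope="session")
def model33():
    return preset("model33")


@pytest.fixture(scope="session")
def model35():
    return preset("model35")


@pytest.fixture(scope="session")
def model36():
    return preset("model36")
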