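import pytest

from carevl import base_case, default_registry


@pytest.fixture(scope="session")
def registry():
    return default_registry()


@pytest.fixture(scope="session")
def params():
    return base_case()
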