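import pytest

from cctecea import default_parameters


@pytest.fixture(scope="session")
def params():
    """Packaged default parameter set (read-only across the session)."""
    return default_parameters()


@pytest.fixture()
def params_copy(params):
    """Mutable copy of the defaults for tests that tweak parameters."""
    return params.copy()
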