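import logging

import pytest

from copdcea.parameters import default_parameters

logging.getLogger("copdcea").setLevel(logging.ERROR)


@pytest.fixture()
def params():
    """A fresh default parameter set (mutable per test)."""
    return default_parameters()


@pytest.fixture(scope="session")
def session_params():
    """Shared read-only default parameter set."""
    return default_parameters()
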