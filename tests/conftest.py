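import pytest

from ervkit import load_canonical
from ervkit.putein import load_env_cds, load_env_reference


@pytest.fixture(scope="session")
def model():
    return load_canonical()


@pytest.fixture(scope="session")
def env_reference():
    protein, domains = load_env_reference()
    return protein


@pytest.fixture(scope="session")
def env_domains():
    _, domains = load_env_reference()
    return domains


@pytest.fixture(scope="session")
def env_cds():
    return load_env_cds()
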