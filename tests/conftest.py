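import pytest

from chemlink.fixtures import FixtureSpec, build_store
from chemlink.schema import default_schema


@pytest.fixture(scope="session")
def schema():
    return default_schema()


@pytest.fixture(scope="session")
def planted():
    """One generated fixture store with its ground-truth manifest."""
    return build_store(FixtureSpec(seed=7))


@pytest.fixture()
def store(planted):
    return planted[0]


@pytest.fixture()
def manifest(planted):
    return planted[1]
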