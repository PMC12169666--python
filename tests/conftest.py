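import pytest

from ronsff.params import default_database


@pytest.fixture(scope="session")
def db():
    return default_database()


@pytest.fixture(scope="session")
def hoono(db):
    return db.get_topology("HOONO")


@pytest.fixture(scope="session")
def h2o2(db):
    return db.get_topology("H2O2")
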