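import pytest

from hboc import EngineConfig, carrier_fixture_variants, load_fixture


@pytest.fixture(scope="session")
def carriers_df():
    return load_fixture("carriers_table1")


@pytest.fixture(scope="session")
def patients_df():
    return load_fixture("patients_table3")


@pytest.fixture(scope="session")
def tumors_df():
    return load_fixture("tumors_table4")


@pytest.fixture(scope="session")
def carrier_variants():
    return carrier_fixture_variants()


@pytest.fixture(scope="session")
def engine_config():
    return EngineConfig()
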