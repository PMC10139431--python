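import pytest

from mrkit import EXPOSURE_TRAIT, build_instrument_set, load_table1

MATURE_TNK = "Mature T/NK-cell lymphomas"


@pytest.fixture(scope="session")
def table1():
    return load_table1()


@pytest.fixture(scope="session")
def exposure_records(table1):
    return table1[EXPOSURE_TRAIT]


@pytest.fixture(scope="session")
def tnk_instruments(table1, exposure_records):
    """The 11 harmonized instruments of the headline analysis."""
    return build_instrument_set(
        exposure_records, table1[MATURE_TNK], outcome_id=MATURE_TNK
    )
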