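import pytest

from catwalk.crosswalk import DEFAULT_BANDS, band_windows
from catwalk.io import load_table1_conversion, load_table2_items
from catwalk.rasch import ItemBank, ItemDefinition


@pytest.fixture(scope="session")
def table1():
    """The packaged abbreviated score-to-logit conversion table."""
    return load_table1_conversion()


@pytest.fixture(scope="session")
def table2_records():
    """The 55 packaged SGRQ-C item severities with printed band membership."""
    return load_table2_items()


@pytest.fixture(scope="session")
def default_windows(table1):
    return band_windows(DEFAULT_BANDS, table1)


@pytest.fixture
def dichotomous_bank():
    """Single dichotomous item at severity zero."""
    item = ItemDefinition("d1", "test", "dichotomous item", (0.0,))
    return ItemBank("test", (item,), centred=True)


@pytest.fixture
def symmetric_poly_bank():
    """One polytomous item with thresholds symmetric about zero."""
    item = ItemDefinition("p1", "test", "polytomous item", (-1.0, 1.0))
    return ItemBank("test", (item,), centred=True)
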