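import numpy as np
import pytest

from glyload.data import load_fixture_table1, load_fixture_table4


@pytest.fixture(scope="session")
def table4():
    """The bundled 24-food study table as (FoodRecord, FoodGlycemicSummary) pairs."""
    return load_fixture_table4()


@pytest.fixture(scope="session")
def cohorts():
    """(validation, development) cohort summaries."""
    return load_fixture_table1()


@pytest.fixture()
def rng():
    return np.random.default_rng(20220510)
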