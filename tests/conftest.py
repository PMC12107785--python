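import numpy as np
import pytest
from hypothesis import settings

from netlife.synthetic import (DEFAULT_LAW, micro_cohort, standard_table,
                               synth_lifetable)

settings.register_profile("repeatable", derandomize=True, deadline=None)
settings.load_profile("repeatable")


@pytest.fixture(scope="session")
def population_table():
    """Exact life table of the default (observed-population) law."""
    return synth_lifetable(DEFAULT_LAW, year=2010)


@pytest.fixture(scope="session")
def std_table():
    """The packaged synthetic relational standard."""
    return standard_table()


@pytest.fixture(scope="session")
def micro():
    """20-record hand-written cohort."""
    return micro_cohort()


@pytest.fixture()
def rng():
    return np.random.default_rng(20240901)
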