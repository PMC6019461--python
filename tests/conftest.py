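import pytest

from igmaf.germline import synthetic_igh_database
from igmaf.preprocess import LayoutConfig
from igmaf.standards import default_layout, design_standard_set


@pytest.fixture(scope="session")
def db():
    return synthetic_igh_database(seed=0)


@pytest.fixture(scope="session")
def layout(db):
    return default_layout(db, seed=0)


@pytest.fixture(scope="session")
def layout_config(layout):
    return LayoutConfig.from_layout(layout)


@pytest.fixture(scope="session")
def small_set(db, layout):
    """A 12-standard spike-in set for fast tests."""
    return design_standard_set(db, layout, n_clones=12, seed=1)


@pytest.fixture(scope="session")
def full_set(db, layout):
    """An 85-standard set over all 48 V genes, as pooled in the protocol."""
    return design_standard_set(db, layout, n_clones=85, seed=1)
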