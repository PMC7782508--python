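import dataclasses

import numpy as np
import pytest

from elmsearch.presets import default_presets
from elmsearch.simulator import SearchFieldConfig


@pytest.fixture(scope="session")
def presets():
    return default_presets()


@pytest.fixture(scope="session")
def small_field():
    """A reduced search field (100 locations, 10-degree diameter) used by
    tests that need many simulated trials."""
    return SearchFieldConfig(n_locations=100, diameter=10.0)


@pytest.fixture(scope="session")
def small_cctelm(presets, small_field):
    return dataclasses.replace(presets["cctelm-default"], field=small_field)


@pytest.fixture(scope="session")
def small_ctelm(presets, small_field):
    return dataclasses.replace(presets["ctelm-default"], field=small_field)


@pytest.fixture(scope="session")
def small_elm(presets, small_field):
    return dataclasses.replace(presets["elm-default"], field=small_field)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
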