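import numpy as np
import pytest

from flyndj.markers import MarkerMap, standard_map


@pytest.fixture
def rng():
    """Fresh deterministic generator per test."""
    return np.random.default_rng(20240901)


@pytest.fixture
def default_map():
    return MarkerMap()


@pytest.fixture
def atomic_map():
    """Six-locus map whose scored intervals are single physical intervals."""
    return standard_map(include_v=False)


@pytest.fixture
def zero_map():
    """Map with no recombination anywhere."""
    return MarkerMap(interval_r=(0.0,) * 6)
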