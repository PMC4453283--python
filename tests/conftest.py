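import numpy as np
import pytest

from agecsf import ViewingConditions


@pytest.fixture
def owsley_conditions():
    """Photopic binocular setup: 100 cd/m^2, 5.5 deg square field."""
    return ViewingConditions(luminance=100.0, field_x=5.5, eyes=2)


@pytest.fixture
def keesey_conditions():
    """Photopic monocular setup: 60 cd/m^2, 7 deg square field."""
    return ViewingConditions(luminance=60.0, field_x=7.0, eyes=1)


@pytest.fixture
def frequency_ladder():
    return np.array([0.5, 1.0, 2.0, 4.0, 8.0, 16.0, 22.0])


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
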