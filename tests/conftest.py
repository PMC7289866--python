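import numpy as np
import pytest

from snapmech.morphometry import MandibleMorphometry
from snapmech.synthetic_data import SimulationConfig


@pytest.fixture
def mandible_split():
    """Hand-checked 10/18 μg split over a 1.06 mm anterior part."""
    return MandibleMorphometry(m_a1=10e-9, m_a2=18e-9, l_a=1.06e-3)


@pytest.fixture
def cohort_config():
    return SimulationConfig(seed=11, n_individuals=17, n_events=92)


@pytest.fixture
def rng():
    return np.random.default_rng(42)
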