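import numpy as np
import pytest

from gvarcomp import DesignSpec, DistributionSpec


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def study_design():
    """The 100 persons x 20 items design of the main study."""
    return DesignSpec(100, 20)


@pytest.fixture
def normal_spec():
    return DistributionSpec.normal()


@pytest.fixture
def hand_matrix():
    """2 x 2 worked example with mean squares (6.25, 2.25, 0.25)."""
    return np.array([[1.0, 2.0], [3.0, 5.0]])
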