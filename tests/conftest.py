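import numpy as np
import pytest

from srinc import DiseaseModel, default_sr_parameters
from srinc.incidence_model import DEFAULT_CONSTANTS


@pytest.fixture(scope="session")
def constants():
    return DEFAULT_CONSTANTS


@pytest.fixture(scope="session")
def sr_params():
    """The calibrated SR rates shipped with the package."""
    return default_sr_parameters()


@pytest.fixture(scope="session")
def canonical_model():
    """The representative age-related disease used throughout: threshold
    14 X-units, 10% susceptible."""
    return DiseaseModel(Xc_mean=14.0, s=0.1)


@pytest.fixture(scope="session")
def age_grid():
    return np.arange(0.0, 110.5, 1.0)
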