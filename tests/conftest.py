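import numpy as np
import pytest

from glucogate.bands import default_library
from glucogate.gating import skin_rejection_pipeline
from glucogate.simulate import AcquisitionConfig, simulate_experiment
from glucogate.skin import make_default_skin


@pytest.fixture(scope="session")
def library():
    return default_library()


@pytest.fixture(scope="session")
def skin():
    return make_default_skin()


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def acq():
    return AcquisitionConfig()


@pytest.fixture(scope="session")
def dataset():
    """One full default glucose-tolerance-test dataset (both locations)."""
    return simulate_experiment(seed=1)


@pytest.fixture(scope="session")
def p1_result(dataset):
    """Skin-rejection pipeline output at the vascular point of `dataset`."""
    return skin_rejection_pipeline(dataset, "P1")
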