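import numpy as np
import pytest

from tamflow.synthdata import default_phantom_config, generate_phantom
from tamflow.tracking import estimate_orientations


@pytest.fixture(scope="session")
def phantom_config():
    return default_phantom_config(rng_seed=0)


@pytest.fixture(scope="session")
def phantom(phantom_config):
    """(TensorVolume, LabelVolume, csf ScalarVolume) of the study phantom."""
    return generate_phantom(phantom_config)


@pytest.fixture(scope="session")
def orientation_field(phantom):
    tensors, _, _ = phantom
    return estimate_orientations(tensors)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
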