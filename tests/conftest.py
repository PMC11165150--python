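import numpy as np
import pytest

from pvtfatigue import ModelParams


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def cmf_params():
    """CMF at the scale of per-subject fits to a 10-minute vigil."""
    return ModelParams(variant="cmf", upsilon=3.82, lambda_ml=0.88, phi=0.057,
                       rho=-0.20, kappa=-0.15)


@pytest.fixture
def gamma2_params():
    return ModelParams(variant="gamma2", upsilon=4.0, lambda_ml=0.93, phi=0.058)
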