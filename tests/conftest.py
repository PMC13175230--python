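import numpy as np
import pytest

from ivimkit import ORGANS, IVIMParams, get_preset


@pytest.fixture(scope="session")
def presets():
    return {organ: get_preset(organ) for organ in ORGANS}


@pytest.fixture(scope="session")
def kidney(presets):
    return presets["kidney"]


@pytest.fixture
def kidney_params():
    """A kidney-like parameter set used across fitting tests."""
    return IVIMParams(f=0.15, D=1.5e-3, Dstar=50e-3, S0=1.0)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
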