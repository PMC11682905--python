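import numpy as np
import pytest

from alloclone import ModelParams, calibrate_homeostasis, make_graft


@pytest.fixture(scope="session")
def model():
    """Calibrated reference model (baseline feedback variant)."""
    return calibrate_homeostasis(ModelParams())


@pytest.fixture(scope="session")
def reference_graft(model):
    """The reference transplant: 4.7e6 CD34+ cells/kg, wildtype only."""
    return make_graft(model, 4.7e6)


@pytest.fixture(scope="session")
def equilibrium(model):
    return model.equilibrium.copy()
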