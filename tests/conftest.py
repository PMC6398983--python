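import numpy as np
import pytest

from smaddyn.models import (default_feedback_params, default_receptor_params,
                            default_depletion_params)


@pytest.fixture(scope="session")
def smad4_params():
    return default_feedback_params("SMAD4")


@pytest.fixture(scope="session")
def smad23_params():
    return default_feedback_params("SMAD2/3")


@pytest.fixture(scope="session")
def receptor_params():
    return default_receptor_params()


@pytest.fixture(scope="session")
def depletion_params():
    return default_depletion_params()


@pytest.fixture(scope="session")
def t12():
    """0-12 hr grid at 0.01 hr."""
    return np.arange(0.0, 12.0 + 1e-9, 0.01)


@pytest.fixture(scope="session")
def t24():
    return np.arange(0.0, 24.0 + 1e-9, 0.01)
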