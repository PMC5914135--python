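import numpy as np
import pytest

from suprafit import ThermoParams, paper_presets, preset_observable_coefficients


@pytest.fixture(scope="session")
def presets():
    return paper_presets()


@pytest.fixture(scope="session")
def coeffs():
    return preset_observable_coefficients()


@pytest.fixture(scope="session")
def study_params(presets):
    """Equilibrium constants of the study system at 293 K."""
    return presets.thermo


@pytest.fixture
def fine_grid():
    """0.1 nm grid over the Qy region for sub-percent descriptor checks."""
    return np.arange(550.0, 820.0, 0.1)
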