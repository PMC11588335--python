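import numpy as np
import pytest

from thermorich import EnsembleTPC, ThermalContext


@pytest.fixture
def ctx13():
    """Reference context at 13 °C, the presets' convention."""
    return ThermalContext(t_ref=286.15)


@pytest.fixture
def experimental_ens():
    return EnsembleTPC(mu_b0=0.0, mu_e=1.0, var_b0=0.95, var_e=0.25, cov_b0e=-0.42)


@pytest.fixture
def rng():
    return np.random.default_rng(20260)
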