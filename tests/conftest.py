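import numpy as np
import pytest

from condmech import synth


@pytest.fixture
def material():
    """Reference droplet: E = 2 Pa, dashpot 0.1 Pa*s, gamma = 1 pN/um,
    theta0 = 0.5, diameter 5 um -> analytic crossover 3.1831 Hz."""
    return synth.MaterialTruth(
        plateau_modulus_E=2.0,
        dashpot_viscosity=0.1,
        surface_tension_gamma=1.0,
        contact_parameter_theta0=0.5,
        droplet_diameter_D=5.0,
        medium_viscosity=1e-3,
    )


@pytest.fixture
def traps():
    """Reference traps: k1 = k2 = 50 pN/um, 5 kHz, octave sweep, no noise."""
    return synth.TrapTruth(k1=50.0, k2=50.0, seed=0)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
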