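import numpy as np
import pytest

from siglognorm.model import LognormalComponent
from siglognorm.synth import ParamSpec, RoleConfig, default_population_config


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def component():
    return LognormalComponent(t0=0.2, D=200.0, mu=-1.4, sigma=0.3,
                              theta_s=0.5, theta_e=0.3)


@pytest.fixture
def small_config():
    """Tiny population for fast trial-level tests."""
    return default_population_config(n_participants=3, strokes_per_test=2,
                                     oscillation_duration_s=2.0,
                                     sample_rate_hz=100.0)


def fixed_role(t0, D, mu, sigma, theta_s=0.0, theta_e=0.0):
    """Degenerate (zero-SD) role distribution for deterministic trials."""
    return RoleConfig(t0=ParamSpec(t0, 0.0), D=ParamSpec(D, 0.0),
                      mu=ParamSpec(mu, 0.0), sigma=ParamSpec(sigma, 0.0),
                      theta_s=ParamSpec(theta_s, 0.0),
                      theta_e=ParamSpec(theta_e, 0.0))
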