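import pytest
from hypothesis import HealthCheck, settings

from dropsolid import COCOA_BUTTER, simulate

settings.register_profile(
    "default", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

# Chamber-experiment inputs: 2 mm droplet at 318 K, 83 cm/s air at 1 bar.
BASELINE = dict(d=2e-3, T_init=318.0, Ta=277.0, Vdg=0.83, p=1e5)
COLD = dict(d=2e-3, T_init=318.0, Ta=263.0, Vdg=0.83, p=1e5)


@pytest.fixture(scope="session")
def cb():
    return COCOA_BUTTER


@pytest.fixture(scope="session")
def baseline_traj(cb):
    """2 mm droplet cooling into a 277 K ambient (inside the freezing window)."""
    return simulate(mat=cb, **BASELINE)


@pytest.fixture(scope="session")
def cold_traj(cb):
    """Same droplet with a 263 K ambient: full solidification, then tempering."""
    return simulate(mat=cb, **COLD)
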