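import pytest
from hypothesis import HealthCheck, settings

from tethercap import ScaledGeometry, TetherModel

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

SQRT3 = 3.0**0.5


@pytest.fixture
def default_model() -> TetherModel:
    """a = b = D = T = 1 (the nondimensional unit system), N = 10."""
    return TetherModel(N=10)


@pytest.fixture
def unit_geometry() -> ScaledGeometry:
    """The reference shell (a_bar, R_bar, Rstar_bar) = (1, sqrt(3), 3)."""
    return ScaledGeometry(1.0, SQRT3, 3.0)
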