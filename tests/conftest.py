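import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from ipabilayer import IPAComposition, SyntheticSpec, generate_trajectory

settings.register_profile(
    "default",
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_trajectory():
    """A quick 16-molecule, 60-frame synthetic bilayer shared across tests."""
    spec = SyntheticSpec(
        composition=IPAComposition(12, 10),
        n_per_leaflet=8,
        n_frames=60,
        p_gauche=0.2,
        tilt_theta0=20.0,
        tilt_chi=40.0,
        mean_area=0.45 * 8,
        area_variance=1e-4,
        seed=42,
    )
    traj, gt = generate_trajectory(spec)
    return traj, gt
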