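import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20240601)


@pytest.fixture(scope="session")
def tree_phantom():
    """One seeded random-tree phantom with ground truth, shared per session."""
    from angiokit.phantoms import VesselPhantomSpec, generate_vessel_phantom

    spec = VesselPhantomSpec(
        grid_shape=(64, 200, 200),
        voxel_size=(1.0, 1.0, 1.0),
        topology="random_tree",
        tube_radius_um=3.0,
        n_segments=12,
        segment_length_um=35.0,
        rng_seed=0,
    )
    return generate_vessel_phantom(spec)
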