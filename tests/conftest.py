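import numpy as np
import pytest

from doct import (
    AcquisitionMeta,
    EdgeRing,
    PhantomSpec,
    TimeSeriesStack,
    WelchParams,
    compute_dynamics_maps,
    generate_phantom,
)


@pytest.fixture(scope="session")
def small_meta() -> AcquisitionMeta:
    return AcquisitionMeta(n_frames=128, n_axial=32, n_lateral=32)


@pytest.fixture(scope="session")
def random_stack(small_meta) -> TimeSeriesStack:
    rng = np.random.default_rng(42)
    values = rng.random((128, 32, 32)) + 0.5
    return TimeSeriesStack(values=values, meta=small_meta)


@pytest.fixture(scope="session")
def phantom_spec() -> PhantomSpec:
    """Reduced-size two-layer phantom used across the suite."""
    return PhantomSpec(
        shape=(128, 128),
        outer_radii=(140.0, 140.0),
        core_radii=(70.0, 70.0),
        n_frames=256,
        seed=7,
    )


@pytest.fixture(scope="session")
def phantom(phantom_spec):
    return generate_phantom(phantom_spec)


@pytest.fixture(scope="session")
def phantom_maps(phantom):
    stack, _, _ = phantom
    return compute_dynamics_maps(stack, WelchParams(segment_length=128))


@pytest.fixture(scope="session")
def ringed_phantom():
    spec = PhantomSpec(
        shape=(128, 128),
        outer_radii=(140.0, 140.0),
        core_radii=(70.0, 70.0),
        n_frames=256,
        seed=11,
        edge_ring=EdgeRing(enabled=True),
    )
    return generate_phantom(spec)
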