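import numpy as np
import pytest

from ventidose.phantom import (
    CohortSimSpec,
    PhantomSpec,
    generate_phantom_pair,
    simulate_cohort,
)

FV = [f"V{x}" for x in range(5, 65, 5)]


@pytest.fixture(scope="session")
def fv_columns():
    return list(FV)


@pytest.fixture(scope="session")
def noise_free_phantom():
    """Default breathing phantom without intensity noise."""
    spec = PhantomSpec(noise_sd=0.0)
    exhale, inhale, truth, lung = generate_phantom_pair(spec)
    return spec, exhale, inhale, truth, lung


@pytest.fixture(scope="session")
def affine_phantom():
    """Uniform-expansion phantom: u(x) = 0.1·(x − c), Jacobian 1.1³ = 1.331."""
    spec = PhantomSpec(noise_sd=0.0, affine=0.1 * np.eye(3))
    exhale, inhale, truth, lung = generate_phantom_pair(spec)
    return spec, exhale, inhale, truth, lung


@pytest.fixture(scope="session")
def cohort200():
    return simulate_cohort(CohortSimSpec(n_patients=200, seed=5))


@pytest.fixture(scope="session")
def cohort120():
    return simulate_cohort(CohortSimSpec(n_patients=120, seed=21))


def random_smooth_field(shape=(14, 12, 10), spacing=(2.0, 2.5, 3.0), seed=0, amp=2.0):
    """Band-limited random displacement field (smooth on the voxel scale)."""
    rng = np.random.default_rng(seed)
    from ventidose.grids import DisplacementField, ImageGrid

    grid = ImageGrid(values=np.zeros(shape), spacing=spacing)
    pts = grid.world_grid()
    ext = (np.asarray(shape) - 1) * np.asarray(spacing)
    u = np.zeros(shape + (3,))
    for comp in range(3):
        for _ in range(4):
            k = rng.uniform(0.5, 1.5, 3) * 2 * np.pi / ext
            phase = rng.uniform(0, 2 * np.pi)
            u[..., comp] += (
                amp
                * rng.normal()
                * np.sin(k[0] * pts[..., 0] + k[1] * pts[..., 1] + k[2] * pts[..., 2] + phase)
            )
    return DisplacementField(vectors=u, spacing=spacing)
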