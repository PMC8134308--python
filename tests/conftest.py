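import numpy as np
import pytest

from contraplane import PhantomSpec, StandardPlaneFrame, VolumeGrid, generate_phantom


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random rotation matrix (QR-based, det +1)."""
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q


def random_frame(rng: np.random.Generator, box_mm=(10.0, 50.0)) -> StandardPlaneFrame:
    rot = random_rotation(rng)
    p = rng.uniform(*box_mm, size=3)
    return StandardPlaneFrame(p, rot[:, 0], rot[:, 1], rot[:, 2])


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def unit_grid_21():
    return VolumeGrid((21, 21, 21), (1.0, 1.0, 1.0), (0.0, 0.0, 0.0))


@pytest.fixture(scope="session")
def unilateral_sample():
    """One desk-scale unilateral phantom, shared across read-only tests."""
    return generate_phantom(PhantomSpec(seed=42))


@pytest.fixture(scope="session")
def bilateral_sample():
    from contraplane.phantom import DEFAULT_BILATERAL_GRID

    return generate_phantom(PhantomSpec(grid=DEFAULT_BILATERAL_GRID, n_ankles=2, seed=7))
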