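import numpy as np
import pytest

from footkin import TrajectorySet, default_geometry


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random proper rotation via QR decomposition."""
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20200807)


@pytest.fixture(scope="session")
def geometry():
    return default_geometry()


@pytest.fixture
def aligned_traj() -> TrajectorySet:
    """Markers whose hallux-style frame is exactly lab-aligned (one frame)."""
    return TrajectorySet(
        {
            "H1": np.array([[0.0, 0.0, 0.0]]),
            "P1": np.array([[50.0, 0.0, 0.0]]),
            "H5": np.array([[0.0, 0.0, 60.0]]),
        },
        rate=100.0,
    )
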