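import numpy as np
import pytest

from semirigid import STDDVMatrix, Trajectory, worked_example_matrix


@pytest.fixture
def worked_matrix() -> STDDVMatrix:
    """3-atom matrix with S_12 = 0.1 and S_13 = S_23 = 1.0.

    Its unique 2-cluster ground state is {0, 1}, {2} with q = 0.2.
    """
    return worked_example_matrix()


def make_random_matrix(n: int, seed: int, scale: float = 1.0) -> STDDVMatrix:
    """Random symmetric nonnegative matrix with zero diagonal."""
    rng = np.random.default_rng(seed)
    v = np.zeros((n, n))
    iu = np.triu_indices(n, k=1)
    v[iu] = rng.uniform(0.01, scale, iu[0].size)
    v += v.T
    return STDDVMatrix(v)


def random_rigid_motion(rng: np.random.Generator):
    """Uniformly random rotation matrix and a random translation [nm]."""
    from scipy.spatial.transform import Rotation

    rot = Rotation.random(rng=rng).as_matrix()
    shift = rng.normal(0.0, 2.0, 3)
    return rot, shift


@pytest.fixture
def static_trajectory() -> Trajectory:
    """Twenty identical frames of a 6-atom structure."""
    rng = np.random.default_rng(7)
    frame = rng.normal(0.0, 1.0, (6, 3))
    return Trajectory(np.repeat(frame[None], 20, axis=0))
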