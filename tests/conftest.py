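import numpy as np
import pytest

from cortexmesh.meshwork_synthesis import Compartment, MeshworkModel
from cortexmesh.trajectory import Trajectory, TrajectoryEnsemble


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def grid_mesh():
    """A 3x3 grid of 2x2 μm compartments on a 6x6 μm region."""
    fences = [(0, 0, 6, 0), (6, 0, 6, 6), (6, 6, 0, 6), (0, 6, 0, 0)]
    for c in (2.0, 4.0):
        fences.append((c, 0.0, c, 6.0))
        fences.append((0.0, c, 6.0, c))
    comps = [
        Compartment(i * 2.0, j * 2.0, (i + 1) * 2.0, (j + 1) * 2.0)
        for i in range(3)
        for j in range(3)
    ]
    return MeshworkModel((6.0, 6.0), fences, comps)


def make_random_trajectory(rng, n=100, dt=0.02, track_id="t0"):
    pos = np.cumsum(rng.normal(0, 0.1, size=(n, 2)), axis=0)
    return Trajectory(track_id, np.arange(n) * dt, pos)


@pytest.fixture
def random_trajectory(rng):
    return make_random_trajectory(rng)


@pytest.fixture
def small_ensemble(rng):
    trajs = [make_random_trajectory(rng, n=60, track_id=f"t{i}") for i in range(5)]
    return TrajectoryEnsemble(trajs, frame_interval=0.02)
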