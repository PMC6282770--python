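import numpy as np
import pytest

from nurbstrack.grid import TrackingParams, VectorField, VoxelDirectionSet, VoxelGrid
from nurbstrack.peaks import default_sampling


@pytest.fixture(scope="session")
def sampling64():
    return default_sampling(64)


@pytest.fixture
def params():
    return TrackingParams()


def uniform_field(dims=(20, 20, 20), direction=(1.0, 0.0, 0.0), voxel=1.0):
    """Every voxel carries the same single axis with d = 1."""
    grid = VoxelGrid(dims, (voxel,) * 3)
    v = np.asarray(direction, dtype=float)
    v = v / np.linalg.norm(v)
    sets = {idx: VoxelDirectionSet(v[None, :], [1.0]) for idx in grid.all_indices()}
    return VectorField(grid, sets)


def random_small_field(rng, max_dim=6, max_dirs=2):
    """A random little vector field for oracle cross-checks."""
    dims = tuple(int(rng.integers(3, max_dim + 1)) for _ in range(3))
    grid = VoxelGrid(dims)
    sets = {}
    for idx in grid.all_indices():
        n = int(rng.integers(0, max_dirs + 1))
        if n == 0:
            continue
        v = rng.standard_normal((n, 3))
        v /= np.linalg.norm(v, axis=1, keepdims=True)
        d = rng.uniform(0.1, 1.0, n)
        sets[idx] = VoxelDirectionSet(v, d / d.sum())
    fa = rng.uniform(0.0, 1.0, dims)
    return VectorField(grid, sets, fa=fa)
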