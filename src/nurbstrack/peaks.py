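"""ODF peak extraction: turn per-voxel spherical samples into fiber axes.

An orientation distribution function (ODF) is a non-negative function on the
sphere whose local maxima mark the fiber axes crossing a voxel.  Peaks are
found discretely over the sampling shell: a vertex is kept when it is a strict
local maximum over its triangulation neighborhood *and* strictly above the
per-voxel mean ODF value (the mean threshold suppresses spurious noise peaks).
Retained values, normalized to sum to 1 within the voxel, become the diffusion
probabilities ``d_i``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.spatial import ConvexHull

from .grid import VectorField, VoxelDirectionSet, VoxelGrid

__all__ = [
    "SphereSampling",
    "OdfField",
    "fibonacci_sphere",
    "local_maxima_above_mean",
    "generalized_fa",
    "build_vector_field",
]

# axial tolerance below which two maxima are considered the same fiber axis
_MERGE_DEG = 5.0


@dataclass(frozen=True)
class SphereSampling:
    """A triangulated set of unit directions on the sphere.

    ``adjacency[i]`` lists the vertex indices sharing a triangulation edge
    with vertex ``i``.  Built from the convex hull of the vertex cloud, which
    for points on a sphere is exactly the Delaunay triangulation of the shell.
    """

    vertices: np.ndarray
    adjacency: tuple[tuple[int, ...], ...]

    def __post_init__(self) -> None:
        v = np.asarray(self.vertices, dtype=float)
        if v.ndim != 2 or v.shape[1] != 3:
            raise ValueError("vertices must be N x 3")
        if np.any(np.abs(np.linalg.norm(v, axis=1) - 1.0) > 1e-6):
            raise ValueError("sampling vertices must be unit vectors")
        if any(len(nb) < 3 for nb in self.adjacency):
            raise ValueError("every sampling vertex needs at least 3 neighbors")
        object.__setattr__(self, "vertices", v)

    @classmethod
    def from_vertices(cls, vertices: np.ndarray) -> "SphereSampling":
        vertices = np.asarray(vertices, dtype=float)
        norms = np.linalg.norm(vertices, axis=1, keepdims=True)
        if np.any(norms == 0):
            raise ValueError("zero vector in direction table")
        vertices = vertices / norms
        hull = ConvexHull(vertices)
        nbrs: list[set[int]] = [set() for _ in range(len(vertices))]
        for a, b, c in hull.simplices:
            nbrs[a].update((b, c))
            nbrs[b].update((a, c))
            nbrs[c].update((a, b))
        adjacency = tuple(tuple(sorted(s)) for s in nbrs)
        return cls(vertices, adjacency)

    def __len__(self) -> int:
        return self.vertices.shape[0]

    def max_neighbor_angle(self) -> float:
        """Largest angular spacing (radians) between adjacent vertices."""
        worst = 0.0
        for i, nbrs in enumerate(self.adjacency):
            for j in nbrs:
                c = float(np.clip(np.dot(self.vertices[i], self.vertices[j]), -1, 1))
                worst = max(worst, math.acos(c))
        return worst


def fibonacci_sphere(n: int) -> np.ndarray:
    """``n`` near-uniformly distributed unit vectors.

    Even ``n`` yields an antipodally symmetric set (a golden-spiral lattice on
    the upper hemisphere plus its mirror image), matching the axial symmetry
    of ODFs; odd ``n`` falls back to the plain whole-sphere spiral.
    """
    if n < 4:
        raise ValueError("need at least 4 points for a spherical triangulation")
    phi = (1 + math.sqrt(5)) / 2
    if n % 2 == 0:
        m = n // 2
        i = np.arange(m, dtype=float)
        z = 1 - (2 * i + 1) / (2 * m)  # upper hemisphere band centers
        theta = 2 * math.pi * i / phi
        r = np.sqrt(np.maximum(0.0, 1 - z * z))
        upper = np.column_stack([r * np.cos(theta), r * np.sin(theta), z])
        return np.vstack([upper, -upper])
    i = np.arange(n, dtype=float)
    z = 1 - (2 * i + 1) / n
    theta = 2 * math.pi * i / phi
    r = np.sqrt(np.maximum(0.0, 1 - z * z))
    return np.column_stack([r * np.cos(theta), r * np.sin(theta), z])


def default_sampling(n: int = 64) -> SphereSampling:
    """The default acquisition-like shell: n orientations spread over the sphere."""
    return SphereSampling.from_vertices(fibonacci_sphere(n))


@dataclass
class OdfField:
    """Per-voxel ODF samples on a shared spherical sampling."""

    grid: VoxelGrid
    sampling: SphereSampling
    values: np.ndarray  # (nx, ny, nz, N) non-negative

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        expected = tuple(self.grid.dims) + (len(self.sampling),)
        if self.values.shape != expected:
            raise ValueError(f"ODF values shape {self.values.shape} != {expected}")
        if np.any(self.values < 0):
            raise ValueError("ODF samples must be non-negative")


def local_maxima_above_mean(values: np.ndarray, sampling: SphereSampling) -> VoxelDirectionSet:
    """Extract fiber axes from one voxel's ODF samples.

    Keeps vertices that are strict local maxima over the triangulation
    neighborhood and strictly above the mean sample value; merges antipodally
    duplicate maxima (axial angle < 5 degrees) keeping the larger value;
    normalizes retained values to probabilities summing to 1, sorted by
    descending probability.
    """
    values = np.asarray(values, dtype=float)
    if values.ndim != 1 or values.shape[0] != len(sampling):
        raise ValueError("values must match the sampling vertex count")
    if values.size == 0 or np.any(np.isnan(values)):
        raise ValueError("ODF samples must be non-empty and free of NaN")
    mean = float(values.mean())
    candidates = [
        i
        for i in range(len(values))
        if values[i] > mean
        and all(values[i] > values[j] for j in sampling.adjacency[i])
    ]
    if not candidates:
        return VoxelDirectionSet.empty()
    # merge near-identical axes, larger value wins
    candidates.sort(key=lambda i: (-values[i], i))
    merge_cos = math.cos(math.radians(_MERGE_DEG))
    kept: list[int] = []
    for i in candidates:
        vi = sampling.vertices[i]
        if all(abs(float(np.dot(vi, sampling.vertices[j]))) < merge_cos for j in kept):
            kept.append(i)
    vals = values[kept]
    return VoxelDirectionSet(sampling.vertices[kept], vals / vals.sum())


def generalized_fa(values: np.ndarray) -> float:
    """ODF-based anisotropy surrogate: ``sqrt(N var / ((N-1)/N rms^2))`` form.

    Computed as ``sqrt( N * sum((psi - mean)^2) / ((N-1) * sum(psi^2)) )``,
    clipped to [0, 1].  Zero for a constant profile, approaching 1 for a
    single spike; invariant to positive scaling.
    """
    values = np.asarray(values, dtype=float)
    if values.ndim != 1 or values.size < 2:
        raise ValueError("need a 1-D sample vector of length >= 2")
    if np.any(values < 0) or not np.any(values > 0):
        raise ValueError("values must be non-negative and not all zero")
    n = values.size
    num = n * float(np.sum((values - values.mean()) ** 2))
    den = (n - 1) * float(np.sum(values**2))
    return float(np.clip(math.sqrt(num / den), 0.0, 1.0))


def build_vector_field(
    odf: OdfField,
    fa: Optional[np.ndarray] = None,
    wm_mask: Optional[np.ndarray] = None,
) -> VectorField:
    """Transform an ODF field into a vector field of fiber axes.

    Peak extraction runs voxelwise inside ``wm_mask`` (everywhere when no mask
    is given).  If no FA volume is supplied, a generalized-FA volume computed
    from the ODF samples is attached instead (0 where the profile is all
    zero).
    """
    dims = tuple(odf.grid.dims)
    if fa is not None and np.asarray(fa).shape != dims:
        raise ValueError("FA shape does not match grid dims")
    if wm_mask is not None and np.asarray(wm_mask).shape != dims:
        raise ValueError("mask shape does not match grid dims")
    sets: dict[tuple[int, int, int], VoxelDirectionSet] = {}
    gfa = None if fa is not None else np.zeros(dims)
    for idx in odf.grid.all_indices():
        vals = odf.values[idx]
        if wm_mask is not None and not wm_mask[idx]:
            continue
        if gfa is not None and np.any(vals > 0):
            gfa[idx] = generalized_fa(vals)
        peaks = local_maxima_above_mean(vals, odf.sampling)
        if len(peaks):
            sets[idx] = peaks
    return VectorField(
        odf.grid,
        sets,
        fa=np.asarray(fa, dtype=float) if fa is not None else gfa,
        wm_mask=np.asarray(wm_mask, dtype=bool) if wm_mask is not None else None,
    )
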