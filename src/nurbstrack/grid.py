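"""Voxel-grid geometry and the shared domain types of the tractography pipeline.

Conventions: 0-based voxel indices; voxel ``(i, j, k)`` occupies the half-open
box ``[origin + i*s, origin + (i+1)*s)`` per axis (``s`` = voxel size in mm);
its center is ``origin + (i + 0.5)*s``.  World units are millimetres.  Grids
are axis-aligned (scaling and translation only; no oblique rotations).

Diffusion directions are axial: ``v`` and ``-v`` denote the same fiber axis,
so every angle comparison in the package uses the axial angle
``min(theta, 180 - theta)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from typing import Iterator, Optional, Sequence

import numpy as np

__all__ = [
    "TerminationReason",
    "VoxelGrid",
    "VoxelDirectionSet",
    "VectorField",
    "TrackingParams",
    "Pathway",
    "voxel_center",
    "neighbors26",
    "point_line_distance",
    "axial_angle",
]

_UNIT_TOL = 1e-9


class TerminationReason(str, Enum):
    """Why a chain / pathway stopped growing."""

    ANGLE = "angle"
    LENGTH = "length"
    FA = "fa"
    NO_CANDIDATE = "no_candidate"
    MASK_EXIT = "mask_exit"


@dataclass(frozen=True)
class VoxelGrid:
    """Axis-aligned voxel lattice in world (mm) coordinates.

    Parameters
    ----------
    dims
        Number of voxels per axis ``(nx, ny, nz)``, each >= 1.
    voxel_size
        Edge lengths in mm, each > 0.
    origin
        World coordinate of the corner of voxel ``(0, 0, 0)``.
    """

    dims: tuple[int, int, int]
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        object.__setattr__(self, "dims", tuple(int(d) for d in self.dims))
        object.__setattr__(self, "voxel_size", tuple(float(s) for s in self.voxel_size))
        object.__setattr__(self, "origin", tuple(float(o) for o in self.origin))
        if len(self.dims) != 3 or any(d < 1 for d in self.dims):
            raise ValueError(f"dims must be three integers >= 1, got {self.dims}")
        if len(self.voxel_size) != 3 or any(s <= 0 for s in self.voxel_size):
            raise ValueError(f"voxel sizes must be > 0, got {self.voxel_size}")

    @property
    def diagonal(self) -> float:
        """Length of one voxel's space diagonal, mm."""
        return float(np.linalg.norm(self.voxel_size))

    def in_bounds(self, idx: Sequence[int]) -> bool:
        return all(0 <= int(i) < d for i, d in zip(idx, self.dims))

    def voxel_center(self, idx: Sequence[int]) -> np.ndarray:
        """World coordinate of the center of voxel ``idx`` (mm)."""
        if not self.in_bounds(idx):
            raise IndexError(f"voxel index {tuple(idx)} outside grid dims {self.dims}")
        return np.asarray(self.origin) + (np.asarray(idx, dtype=float) + 0.5) * np.asarray(
            self.voxel_size
        )

    def voxel_bounds(self, idx: Sequence[int]) -> tuple[np.ndarray, np.ndarray]:
        """Lower and upper corners of the voxel's half-open box."""
        if not self.in_bounds(idx):
            raise IndexError(f"voxel index {tuple(idx)} outside grid dims {self.dims}")
        lo = np.asarray(self.origin) + np.asarray(idx, dtype=float) * np.asarray(self.voxel_size)
        return lo, lo + np.asarray(self.voxel_size)

    def containing_voxel(self, point: Sequence[float]) -> Optional[tuple[int, int, int]]:
        """Voxel whose half-open box contains ``point``, or None if outside."""
        rel = (np.asarray(point, dtype=float) - np.asarray(self.origin)) / np.asarray(
            self.voxel_size
        )
        idx = np.floor(rel).astype(int)
        if all(0 <= i < d for i, d in zip(idx, self.dims)):
            return (int(idx[0]), int(idx[1]), int(idx[2]))
        return None

    def all_indices(self) -> Iterator[tuple[int, int, int]]:
        nx, ny, nz = self.dims
        for i in range(nx):
            for j in range(ny):
                for k in range(nz):
                    yield (i, j, k)

    def neighbors26(self, idx: Sequence[int]) -> list[tuple[int, int, int]]:
        """In-bounds 26-connected neighbors of ``idx`` (excluding ``idx``)."""
        if not self.in_bounds(idx):
            raise IndexError(f"voxel index {tuple(idx)} outside grid dims {self.dims}")
        i0, j0, k0 = (int(v) for v in idx)
        out: list[tuple[int, int, int]] = []
        for di in (-1, 0, 1):
            for dj in (-1, 0, 1):
                for dk in (-1, 0, 1):
                    if di == dj == dk == 0:
                        continue
                    n = (i0 + di, j0 + dj, k0 + dk)
                    if self.in_bounds(n):
                        out.append(n)
        return out


def voxel_center(grid: VoxelGrid, idx: Sequence[int]) -> np.ndarray:
    """World-mm center of voxel ``idx``: ``origin + (idx + 0.5) * voxel_size``."""
    return grid.voxel_center(idx)


def neighbors26(grid: VoxelGrid, idx: Sequence[int]) -> list[tuple[int, int, int]]:
    """In-bounds 26-connected neighborhood (interior voxels have exactly 26)."""
    return grid.neighbors26(idx)


def point_line_distance(p: Sequence[float], a: Sequence[float], u: Sequence[float]) -> float:
    """Perpendicular distance from ``p`` to the infinite line through ``a`` along unit ``u``.

    Invariant under ``u -> -u`` and under joint translation of ``p`` and ``a``.
    """
    u = np.asarray(u, dtype=float)
    if abs(np.linalg.norm(u) - 1.0) > 1e-6:
        raise ValueError("direction u must be a unit vector")
    r = np.asarray(p, dtype=float) - np.asarray(a, dtype=float)
    return float(np.linalg.norm(r - np.dot(r, u) * u))


def axial_angle(u: Sequence[float], v: Sequence[float]) -> float:
    """Angle in radians between fiber *axes* (sign-insensitive), in [0, pi/2]."""
    c = abs(float(np.dot(u, v)))
    return math.acos(min(1.0, c))


class VoxelDirectionSet:
    """Per-voxel fiber axes: unit diffusion directions with probabilities ``d_i``.

    The direction sign carries no meaning (``v`` and ``-v`` are the same axis).
    Probabilities are strictly positive; when produced by peak extraction they
    sum to 1 within the voxel.
    """

    __slots__ = ("directions", "probabilities")

    def __init__(self, directions: np.ndarray, probabilities: np.ndarray) -> None:
        directions = np.atleast_2d(np.asarray(directions, dtype=float))
        probabilities = np.atleast_1d(np.asarray(probabilities, dtype=float))
        if directions.size == 0:
            directions = directions.reshape(0, 3)
            probabilities = probabilities.reshape(0)
        if directions.shape[1] != 3 or directions.shape[0] != probabilities.shape[0]:
            raise ValueError("directions must be n x 3 with matching n probabilities")
        if directions.shape[0]:
            norms = np.linalg.norm(directions, axis=1)
            if np.any(np.abs(norms - 1.0) > 1e-6):
                raise ValueError("all directions must be unit vectors")
            if np.any(probabilities <= 0):
                raise ValueError("probabilities must be strictly positive")
        self.directions = directions
        self.probabilities = probabilities

    @classmethod
    def empty(cls) -> "VoxelDirectionSet":
        return cls(np.zeros((0, 3)), np.zeros(0))

    def __len__(self) -> int:
        return self.directions.shape[0]

    def __iter__(self) -> Iterator[tuple[np.ndarray, float]]:
        for v, d in zip(self.directions, self.probabilities):
            yield v, float(d)

    def __repr__(self) -> str:  # pragma: no cover
        return f"VoxelDirectionSet(n={len(self)})"


_EMPTY_SET = VoxelDirectionSet.empty()


class VectorField:
    """A vector field over a voxel grid: per-voxel direction sets + optional FA/mask.

    ``sets`` is a dict keyed by voxel index; voxels without an entry have an
    empty direction set.  Voxels outside ``wm_mask`` are treated as empty
    regardless of content.
    """

    def __init__(
        self,
        grid: VoxelGrid,
        sets: dict[tuple[int, int, int], VoxelDirectionSet],
        fa: Optional[np.ndarray] = None,
        wm_mask: Optional[np.ndarray] = None,
    ) -> None:
        self.grid = grid
        self.sets = sets
        if fa is not None:
            fa = np.asarray(fa, dtype=float)
            if fa.shape != tuple(grid.dims):
                raise ValueError(f"FA shape {fa.shape} does not match grid dims {grid.dims}")
        if wm_mask is not None:
            wm_mask = np.asarray(wm_mask, dtype=bool)
            if wm_mask.shape != tuple(grid.dims):
                raise ValueError(
                    f"mask shape {wm_mask.shape} does not match grid dims {grid.dims}"
                )
        self.fa = fa
        self.wm_mask = wm_mask

    def directions_at(self, idx: Sequence[int]) -> VoxelDirectionSet:
        key = (int(idx[0]), int(idx[1]), int(idx[2]))
        if self.wm_mask is not None and not self.wm_mask[key]:
            return _EMPTY_SET
        return self.sets.get(key, _EMPTY_SET)

    def fa_at(self, idx: Sequence[int]) -> Optional[float]:
        if self.fa is None:
            return None
        return float(self.fa[int(idx[0]), int(idx[1]), int(idx[2])])

    def in_mask(self, idx: Sequence[int]) -> bool:
        if self.wm_mask is None:
            return True
        return bool(self.wm_mask[int(idx[0]), int(idx[1]), int(idx[2])])

    def passes_fa(self, idx: Sequence[int], fa_th: float) -> bool:
        """True when the voxel's anisotropy clears the stop threshold.

        When no FA volume is attached the test passes (the mask, if any,
        carries the stop role instead).
        """
        fa = self.fa_at(idx)
        return fa is None or fa >= fa_th


@dataclass
class TrackingParams:
    """Stopping thresholds and output settings for tracking.

    theta_th : axial angle threshold between consecutive directions, degrees.
    L_th     : fiber length threshold, mm.
    FA_th    : fractional-anisotropy stop threshold.
    d_th     : line-to-neighbor-center distance threshold, mm; None means
               half the voxel space diagonal of the grid in use.
    step     : output sampling step for fitted pathways, mm.
    mode     : 'nurbs_t', 'nurbs_g' or 'streamline'.
    """

    theta_th: float = 60.0
    L_th: float = 70.0
    FA_th: float = 0.15
    d_th: Optional[float] = None
    step: float = 0.5
    mode: str = "nurbs_t"

    def __post_init__(self) -> None:
        if not 0 < self.theta_th <= 90:
            raise ValueError("theta_th must be in (0, 90] degrees")
        if self.L_th <= 0:
            raise ValueError("L_th must be > 0")
        if not 0 <= self.FA_th < 1:
            raise ValueError("FA_th must be in [0, 1)")
        if self.d_th is not None and self.d_th <= 0:
            raise ValueError("d_th must be > 0")
        if self.step <= 0:
            raise ValueError("step must be > 0")
        if self.mode not in ("nurbs_t", "nurbs_g", "streamline"):
            raise ValueError(f"unknown mode {self.mode!r}")

    def distance_threshold(self, grid: VoxelGrid) -> float:
        return self.d_th if self.d_th is not None else 0.5 * grid.diagonal

    @property
    def theta_rad(self) -> float:
        return math.radians(self.theta_th)


@dataclass
class Pathway:
    """An ordered 3-D polyline in world mm coordinates."""

    points: np.ndarray
    seed_voxel: Optional[tuple[int, int, int]] = None
    termination_reason: Optional[TerminationReason] = None

    def __post_init__(self) -> None:
        self.points = np.atleast_2d(np.asarray(self.points, dtype=float))
        if self.points.shape[0] < 2 or self.points.shape[1] != 3:
            raise ValueError("a pathway needs at least two 3-D points")

    @property
    def length(self) -> float:
        return float(np.sum(np.linalg.norm(np.diff(self.points, axis=0), axis=1)))

    def __len__(self) -> int:
        return self.points.shape[0]
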