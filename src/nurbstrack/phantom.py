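"""Synthetic fiber phantoms with analytically known geometry.

Every phantom starts from one or two piecewise-smooth 3-D curves (straight
line, circular arc, helix, a pair of crossing lines, or a bend).  These are
rasterized onto a voxel grid: a voxel whose center lies within one voxel
space diagonal of a curve — and whose closest curve point is interior, so
the support is a tube that ends flush with the curve — receives that curve's
local unit tangent as a diffusion axis, with probability proportional to
proximity and normalized per voxel; a voxel crossed by two bundles at equal
distance gets two axes with d = (0.5, 0.5).  FA is 0.8 inside the bundle
support and 0.05 outside (cleanly straddling the usual 0.15 stop threshold);
endpoint ROIs are two-voxel-radius balls around each curve end, and the
white-matter mask is the bundle support plus the ROI caps.

Optionally, ODF sample volumes are synthesized as axial peaked mixtures
``sum_j d_j exp(kappa ((v.mu_j)^2 - 1))`` with multiplicative-scale Gaussian
noise, closing the loop with the peak-extraction stage.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .grid import Pathway, VectorField, VoxelDirectionSet, VoxelGrid
from .metrics import BundleTruth
from .peaks import OdfField, SphereSampling

__all__ = ["PhantomSpec", "generate_field", "generate_odf", "truth_pathways"]

_KINDS = ("straight", "arc", "helix", "crossing", "bend")

# bundle / background anisotropy, chosen to straddle the FA stop threshold
FA_BUNDLE = 0.8
FA_BACKGROUND = 0.05


@dataclass
class PhantomSpec:
    """Declarative description of a synthetic phantom.

    All geometry lives on a cubic grid (1 mm voxels, 20^3 by default) and is
    sized to fit with a margin.  ``seed`` fixes all randomness (only the ODF
    noise draws any).
    """

    kind: str = "straight"
    grid: VoxelGrid = field(default_factory=lambda: VoxelGrid((20, 20, 20)))
    radius: float = 10.0  # arc / helix radius, mm
    pitch: float = 10.0  # helix pitch, mm per turn
    crossing_angle: float = 90.0  # degrees
    bend_angle: float = 90.0  # degrees
    odf_sharpness: float = 30.0  # axial kernel concentration kappa
    noise_sigma: float = 0.02  # relative ODF noise level
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ValueError(f"kind must be one of {_KINDS}")
        if self.odf_sharpness <= 0:
            raise ValueError("odf_sharpness (kappa) must be > 0")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")


class _PolylineCurve:
    """Piecewise-linear curve; nearest point and tangent are analytic."""

    def __init__(self, vertices: np.ndarray) -> None:
        self.vertices = np.atleast_2d(np.asarray(vertices, dtype=float))
        seg = np.diff(self.vertices, axis=0)
        self._seg_len = np.linalg.norm(seg, axis=1)
        self._cum = np.concatenate([[0.0], np.cumsum(self._seg_len)])
        self.length = float(self._cum[-1])
        self._seg_dir = seg / self._seg_len[:, None]

    def point(self, s: np.ndarray) -> np.ndarray:
        s = np.atleast_1d(np.clip(s, 0.0, self.length))
        i = np.clip(np.searchsorted(self._cum, s, side="right") - 1, 0, len(self._seg_len) - 1)
        return self.vertices[i] + (s - self._cum[i])[:, None] * self._seg_dir[i]

    def tangent(self, s: np.ndarray) -> np.ndarray:
        s = np.atleast_1d(np.clip(s, 0.0, self.length))
        i = np.clip(np.searchsorted(self._cum, s, side="right") - 1, 0, len(self._seg_len) - 1)
        return self._seg_dir[i]

    def nearest(self, points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Arc-length parameter and distance of the closest curve point."""
        points = np.atleast_2d(points)
        a = self.vertices[:-1]
        d = self.vertices[1:] - a
        len2 = np.einsum("ij,ij->i", d, d)
        t = (np.einsum("pk,sk->ps", points, d) - np.einsum("sk,sk->s", a, d)) / len2
        t = np.clip(t, 0.0, 1.0)
        proj = a[None] + t[..., None] * d[None]
        dist2 = np.einsum("psk,psk->ps", points[:, None] - proj, points[:, None] - proj)
        seg = np.argmin(dist2, axis=1)
        rows = np.arange(points.shape[0])
        s = self._cum[seg] + t[rows, seg] * self._seg_len[seg]
        return s, np.sqrt(dist2[rows, seg])


class _ArcCurve:
    """Circular arc in an axis plane; closed-form nearest point."""

    def __init__(
        self,
        center: np.ndarray,
        radius: float,
        e1: np.ndarray,
        e2: np.ndarray,
        theta0: float,
        theta1: float,
    ) -> None:
        self.center = np.asarray(center, dtype=float)
        self.radius = float(radius)
        self.e1 = np.asarray(e1, dtype=float)
        self.e2 = np.asarray(e2, dtype=float)
        self.theta0, self.theta1 = float(theta0), float(theta1)
        self.length = abs(theta1 - theta0) * radius

    def _theta(self, s: np.ndarray) -> np.ndarray:
        frac = np.clip(s, 0.0, self.length) / self.length
        return self.theta0 + frac * (self.theta1 - self.theta0)

    def point(self, s: np.ndarray) -> np.ndarray:
        th = self._theta(np.atleast_1d(s))[:, None]
        return self.center + self.radius * (np.cos(th) * self.e1 + np.sin(th) * self.e2)

    def tangent(self, s: np.ndarray) -> np.ndarray:
        th = self._theta(np.atleast_1d(s))[:, None]
        t = -np.sin(th) * self.e1 + np.cos(th) * self.e2
        return t * np.sign(self.theta1 - self.theta0)

    def nearest(self, points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        points = np.atleast_2d(points)
        rel = points - self.center
        x = rel @ self.e1
        y = rel @ self.e2
        th = np.arctan2(y, x)
        lo, hi = sorted((self.theta0, self.theta1))
        # wrap into a window centered on the arc before clamping
        mid = 0.5 * (lo + hi)
        th = np.mod(th - (mid - math.pi), 2 * math.pi) + (mid - math.pi)
        th = np.clip(th, lo, hi)
        s = np.abs(th - self.theta0) * self.radius
        d = np.linalg.norm(points - self.point(s), axis=1)
        return s, d


class _HelixCurve:
    """Circular helix around the z axis, arc-length parametrized.

    Nearest points are found by dense sampling refined with a parabolic fit
    through the three bracketing samples of the squared distance.
    """

    def __init__(self, center: np.ndarray, radius: float, pitch: float, height: float) -> None:
        self.center = np.asarray(center, dtype=float)
        self.radius = float(radius)
        self.c = float(pitch) / (2 * math.pi)  # rise per radian
        rate = math.hypot(self.radius, self.c)  # ds/dtheta
        self.theta_max = height / self.c
        self.length = self.theta_max * rate
        self._rate = rate
        self._z0 = -height / 2.0

    def point(self, s: np.ndarray) -> np.ndarray:
        th = np.atleast_1d(np.clip(s, 0, self.length)) / self._rate
        return self.center + np.column_stack(
            [
                self.radius * np.cos(th),
                self.radius * np.sin(th),
                self._z0 + self.c * th,
            ]
        )

    def tangent(self, s: np.ndarray) -> np.ndarray:
        th = np.atleast_1d(np.clip(s, 0, self.length)) / self._rate
        t = np.column_stack(
            [-self.radius * np.sin(th), self.radius * np.cos(th), np.full_like(th, self.c)]
        )
        return t / self._rate

    def nearest(self, points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        points = np.atleast_2d(points)
        n_dense = max(64, int(self.length / 0.05))
        ss = np.linspace(0.0, self.length, n_dense)
        curve = self.point(ss)
        d2 = (
            (points[:, None, :] - curve[None, :, :]) ** 2
        ).sum(axis=2)
        i = np.argmin(d2, axis=1)
        # parabolic refinement on the squared distance around the minimum
        i_c = np.clip(i, 1, n_dense - 2)
        rows = np.arange(points.shape[0])
        ym, y0, yp = d2[rows, i_c - 1], d2[rows, i_c], d2[rows, i_c + 1]
        denom = ym - 2 * y0 + yp
        shift = np.where(np.abs(denom) > 1e-300, 0.5 * (ym - yp) / np.where(denom == 0, 1, denom), 0.0)
        h = ss[1] - ss[0]
        s = np.clip(ss[i_c] + shift * h, 0.0, self.length)
        d = np.linalg.norm(points - self.point(s), axis=1)
        return s, d


def _grid_center(grid: VoxelGrid) -> np.ndarray:
    """Center of the middle voxel — keeps bundle axes on voxel-center lines."""
    mid = tuple(d // 2 for d in grid.dims)
    return grid.voxel_center(mid)


def _truth_curves(spec: PhantomSpec) -> list:
    g = spec.grid
    c = _grid_center(g)
    extent = np.asarray(g.dims, dtype=float) * np.asarray(g.voxel_size)
    half = float(min(extent)) / 2.0 - 2.5  # leave a margin for the bundle halo
    if spec.kind == "straight":
        return [_PolylineCurve([c - [half, 0, 0], c + [half, 0, 0]])]
    if spec.kind == "crossing":
        a = math.radians(spec.crossing_angle)
        u2 = np.array([math.cos(a), math.sin(a), 0.0])
        return [
            _PolylineCurve([c - [half, 0, 0], c + [half, 0, 0]]),
            _PolylineCurve([c - half * u2, c + half * u2]),
        ]
    if spec.kind == "bend":
        a = math.radians(spec.bend_angle)
        u2 = np.array([math.cos(a), math.sin(a), 0.0])
        return [_PolylineCurve([c - [half, 0, 0], c, c + half * u2])]
    if spec.kind == "arc":
        r = spec.radius
        # quarter arc bowing through the grid center region
        center = c + np.array([-r / math.sqrt(2), -r / math.sqrt(2), 0.0])
        arc = _ArcCurve(
            center,
            r,
            np.array([1.0, 0.0, 0.0]),
            np.array([0.0, 1.0, 0.0]),
            math.radians(15.0),
            math.radians(75.0),
        )
        return [arc]
    if spec.kind == "helix":
        height = float(min(extent)) - 5.0
        return [_HelixCurve(c, spec.radius, spec.pitch, height)]
    raise ValueError(f"unknown phantom kind {spec.kind!r}")  # pragma: no cover


def _validate_inside(curves, grid: VoxelGrid) -> None:
    lo = np.asarray(grid.origin)
    hi = lo + np.asarray(grid.dims) * np.asarray(grid.voxel_size)
    for crv in curves:
        pts = crv.point(np.linspace(0, crv.length, 200))
        if np.any(pts < lo) or np.any(pts >= hi):
            raise ValueError("phantom geometry exceeds the grid")


def generate_field(spec: PhantomSpec) -> tuple[VectorField, BundleTruth]:
    """Rasterize the phantom's curves into a vector field plus ground truth."""
    grid = spec.grid
    curves = _truth_curves(spec)
    _validate_inside(curves, grid)
    diag = grid.diagonal
    cap_radius = 2.0 * max(grid.voxel_size)  # two-voxel-radius endpoint caps
    end_tol = 1e-9  # projections clamped to a curve end mark off-tube voxels

    dims = tuple(grid.dims)
    centers = np.array([grid.voxel_center(idx) for idx in grid.all_indices()])
    idx_list = list(grid.all_indices())

    per_curve = []  # (s, dist) arrays per curve, aligned with idx_list
    for crv in curves:
        per_curve.append(crv.nearest(centers))

    sets: dict[tuple[int, int, int], VoxelDirectionSet] = {}
    wm = np.zeros(dims, dtype=bool)
    rois = [
        (np.zeros(dims, dtype=bool), np.zeros(dims, dtype=bool)) for _ in curves
    ]
    ends = [(crv.point(np.array([0.0]))[0], crv.point(np.array([crv.length]))[0]) for crv in curves]
    for row, idx in enumerate(idx_list):
        axes: list[np.ndarray] = []
        weights: list[float] = []
        center = centers[row]
        for ci, crv in enumerate(curves):
            if np.linalg.norm(center - ends[ci][0]) <= cap_radius:
                rois[ci][0][idx] = True
            if np.linalg.norm(center - ends[ci][1]) <= cap_radius:
                rois[ci][1][idx] = True
            s, dist = per_curve[ci][0][row], per_curve[ci][1][row]
            if dist >= diag or s <= end_tol or s >= crv.length - end_tol:
                continue
            t = crv.tangent(np.array([s]))[0]
            t = t / np.linalg.norm(t)
            w = 1.0 - dist / diag
            # same-axis contributions merge (can happen near a bend corner)
            for ai, a in enumerate(axes):
                if abs(float(np.dot(a, t))) > math.cos(math.radians(1.0)):
                    weights[ai] += w
                    break
            else:
                axes.append(t)
                weights.append(w)
        if axes:
            w = np.asarray(weights)
            sets[idx] = VoxelDirectionSet(np.vstack(axes), w / w.sum())
            wm[idx] = True

    fa = np.where(wm, FA_BUNDLE, FA_BACKGROUND)
    mask = wm.copy()
    for roi_a, roi_b in rois:
        mask |= roi_a
        mask |= roi_b
    field = VectorField(grid, sets, fa=fa, wm_mask=mask)
    truth = BundleTruth(
        grid,
        truth_pathways(spec, step=0.5 * min(grid.voxel_size)),
        rois,
        mask,
    )
    return field, truth


def generate_odf(spec: PhantomSpec, sampling: SphereSampling) -> OdfField:
    """Synthesize ODF sample volumes from the phantom's direction field.

    In-bundle voxels get an axial mixture ``sum_j d_j exp(kappa((v.mu_j)^2 - 1))``
    over the sampling vertices; out-of-bundle voxels a flat profile.  Gaussian
    noise of standard deviation ``noise_sigma * |signal|`` is added and the
    result clipped at zero.  Deterministic for a fixed ``spec.seed``.
    """
    field, _ = generate_field(spec)
    rng = np.random.default_rng(spec.seed)
    kappa = spec.odf_sharpness
    verts = sampling.vertices
    dims = tuple(spec.grid.dims)
    values = np.empty(dims + (len(sampling),))
    for idx in spec.grid.all_indices():
        ds = field.sets.get(idx)
        if ds is None or len(ds) == 0:
            profile = np.full(len(sampling), 0.2)
        else:
            dots2 = (verts @ ds.directions.T) ** 2  # (N, n_axes)
            profile = np.exp(kappa * (dots2 - 1.0)) @ ds.probabilities
        if spec.noise_sigma > 0:
            profile = profile + spec.noise_sigma * np.abs(profile) * rng.standard_normal(
                len(sampling)
            )
        values[idx] = np.clip(profile, 0.0, None)
    return OdfField(spec.grid, sampling, values)


def truth_pathways(spec: PhantomSpec, step: float) -> list[Pathway]:
    """The phantom's analytic curves sampled at ``step`` mm, world coordinates."""
    out = []
    for crv in _truth_curves(spec):
        n = max(2, int(round(crv.length / step)) + 1)
        ss = np.linspace(0.0, crv.length, n)
        out.append(Pathway(crv.point(ss)))
    return out
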