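"""Fiber trackers: NURBS-T, NURBS-G and a multidirectional streamline baseline.

Both NURBS modes fit one rational curve per direction chain.  The control
points come from the geometry of the chain itself: for every chain voxel the
diffusion direction (which passes through the voxel center) pierces the
voxel's boundary box at an entry and an exit point.

* NURBS-T uses entry, center and exit per voxel.  Because the three points
  are collinear along the voxel's diffusion direction, the control polygon is
  locally parallel to the fiber axis at every center — the fitted curve's
  tangent there follows the diffusion orientation.
* NURBS-G uses only the entry/exit intersection points, with no tangency
  construction; near-duplicate boundary points across consecutive voxels are
  collapsed for smoothness.

Each control point inherits the diffusion probability ``d_i`` of its source
voxel as its weight (a shared facet point between two voxels averages the
two), and the weight vector is normalized so its maximum is 1 — the scale of
NURBS weights is irrelevant, only their ratios shape the curve.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .chains import ChainNode, DirectionChain, bidirectional_chains
from .grid import (
    Pathway,
    TerminationReason,
    TrackingParams,
    VectorField,
    VoxelGrid,
    axial_angle,
)
from .nurbs import NurbsCurve, make_knot_vector, sample_pathway

__all__ = [
    "ControlSequence",
    "voxel_line_intersections",
    "control_points_T",
    "control_points_G",
    "convert_weights",
    "curve_from_chain",
    "track",
    "track_streamline",
]

logger = logging.getLogger(__name__)


def voxel_line_intersections(
    grid: VoxelGrid, voxel: Sequence[int], direction: Sequence[float]
) -> tuple[np.ndarray, np.ndarray]:
    """Where the center line along ``+/-direction`` crosses the voxel's box.

    Slab (ray-box) method.  Returns ``(entry, exit)``: entry on the
    ``-direction`` side of the center, exit on the ``+direction`` side.  A
    line through the center always crosses the boundary exactly twice.
    """
    u = np.asarray(direction, dtype=float)
    if abs(np.linalg.norm(u) - 1.0) > 1e-6:
        raise ValueError("direction must be unit")
    c = grid.voxel_center(voxel)
    lo, hi = grid.voxel_bounds(voxel)
    t_enter, t_exit = -np.inf, np.inf
    for ax in range(3):
        if u[ax] == 0.0:
            continue  # parallel to this slab; center is inside it
        t1 = (lo[ax] - c[ax]) / u[ax]
        t2 = (hi[ax] - c[ax]) / u[ax]
        t_enter = max(t_enter, min(t1, t2))
        t_exit = min(t_exit, max(t1, t2))
    return c + t_enter * u, c + t_exit * u


@dataclass
class ControlSequence:
    """Ordered control points with their provenance and source chain nodes."""

    points: np.ndarray
    provenance: list[str]  # per point: 'entry' | 'center' | 'exit'
    sources: list[tuple[int, ...]]  # chain-node indices feeding each point

    def __post_init__(self) -> None:
        self.points = np.atleast_2d(np.asarray(self.points, dtype=float))
        if self.points.shape[0] < 2:
            raise ValueError("a control sequence needs at least 2 points")
        if not (len(self.provenance) == len(self.sources) == self.points.shape[0]):
            raise ValueError("provenance/sources must match the point count")

    def __len__(self) -> int:
        return self.points.shape[0]


def _assemble(
    chain: DirectionChain, grid: VoxelGrid, with_centers: bool, merge_tol: float
) -> ControlSequence:
    if not chain.nodes:
        raise ValueError("cannot build control points from an empty chain")
    pts: list[np.ndarray] = []
    prov: list[str] = []
    src: list[tuple[int, ...]] = []
    for k, node in enumerate(chain.nodes):
        entry, exit_ = voxel_line_intersections(grid, node.voxel, node.direction)
        triple = [(entry, "entry"), (exit_, "exit")]
        if with_centers:
            triple.insert(1, (grid.voxel_center(node.voxel), "center"))
        for p, tag in triple:
            if pts and tag == "entry" and k and np.linalg.norm(pts[-1] - p) < merge_tol:
                pts[-1] = 0.5 * (pts[-1] + p)
                src[-1] = src[-1] + (k,)
                continue
            pts.append(p)
            prov.append(tag)
            src.append((k,))
    return ControlSequence(np.vstack(pts), prov, src)


def control_points_T(chain: DirectionChain, grid: VoxelGrid) -> ControlSequence:
    """Entry, center and exit point per chain voxel (tangent-consistent mode).

    Per node the three points are collinear along the node's direction, so
    the control polygon runs parallel to the diffusion axis at every voxel
    center — this is what makes the fitted curve's tangent follow the
    diffusion orientation.  Only analytically coincident boundary points are
    merged (exit_k == entry_{k+1} on a shared facet, to floating point), so
    the collinear triples stay intact.
    """
    return _assemble(chain, grid, with_centers=True, merge_tol=1e-6)


def control_points_G(chain: DirectionChain, grid: VoxelGrid) -> ControlSequence:
    """Only the facet intersection points per chain voxel (general mode).

    With no tangency premise to protect, the exit_k / entry_{k+1} pair across
    each voxel boundary — two descriptions of the same boundary crossing,
    laterally offset when the step is diagonal — is collapsed to its midpoint
    (within half a voxel diagonal).  Keeping both points would force an
    S-bend into the fitted curve at every diagonal step.
    """
    return _assemble(chain, grid, with_centers=False, merge_tol=0.5 * grid.diagonal)


def convert_weights(chain: DirectionChain, sequence: ControlSequence) -> np.ndarray:
    """NURBS weights from diffusion probabilities.

    Every control point inherits the ``d_i`` of its source node (a merged
    facet point shared by nodes ``k`` and ``k+1`` receives their average);
    the vector is then normalized so its maximum is 1.
    """
    probs = [n.probability for n in chain.nodes]
    if any(p <= 0 for p in probs):
        raise ValueError("diffusion probabilities must be > 0")
    w = np.array([np.mean([probs[k] for k in srcs]) for srcs in sequence.sources])
    return w / w.max()


def curve_from_chain(
    chain: DirectionChain, grid: VoxelGrid, mode: str
) -> Optional[NurbsCurve]:
    """Fit one rational curve to a chain; None when too short to fit.

    Cubic by default; when the control sequence holds fewer than 4 points the
    degree drops to ``n_ctrl - 1`` so the order rule (points >= order) still
    holds.  Chains yielding fewer than 2 control points are discarded.
    """
    if mode not in ("nurbs_t", "nurbs_g"):
        raise ValueError(f"unknown NURBS mode {mode!r}")
    if not chain.nodes:
        return None
    seq = control_points_T(chain, grid) if mode == "nurbs_t" else control_points_G(chain, grid)
    n_ctrl = len(seq)
    if n_ctrl < 2:
        return None
    degree = min(3, n_ctrl - 1)
    weights = convert_weights(chain, seq)
    knots = make_knot_vector(n_ctrl, degree)
    return NurbsCurve(degree, seq.points, weights, knots)


def track(
    seeds: Sequence[Sequence[int]],
    field: VectorField,
    params: TrackingParams,
) -> list[Pathway]:
    """NURBS tracking: seeds -> two-sided chains -> rational curves -> pathways.

    One pathway per (seed, seed axis); deterministic output order.  Seeds
    with no directions, outside the mask, or below ``FA_th`` are skipped with
    a logged warning.
    """
    if params.mode == "streamline":
        return track_streamline(seeds, field, params)
    pathways: list[Pathway] = []
    n_skipped = 0
    for seed in seeds:
        seed = tuple(int(v) for v in seed)
        if (
            not field.grid.in_bounds(seed)
            or not field.in_mask(seed)
            or len(field.directions_at(seed)) == 0
            or not field.passes_fa(seed, params.FA_th)
        ):
            n_skipped += 1
            continue
        for chain in bidirectional_chains(seed, field, params):
            curve = curve_from_chain(chain, field.grid, params.mode)
            if curve is None:
                continue
            pathways.append(
                sample_pathway(
                    curve,
                    params.step,
                    seed_voxel=seed,
                    termination_reason=chain.termination_reason,
                )
            )
    if n_skipped:
        logger.warning("skipped %d invalid seed voxel(s)", n_skipped)
    if not pathways:
        logger.warning("tracking produced no pathways")
    return pathways


def _integrate_side(
    p0: np.ndarray,
    u0: np.ndarray,
    field: VectorField,
    params: TrackingParams,
    h: float,
    budget: float,
) -> tuple[list[np.ndarray], TerminationReason]:
    pts = [p0.copy()]
    u = u0.copy()
    length = 0.0
    reason = TerminationReason.NO_CANDIDATE
    while True:
        if length + h > budget:
            reason = TerminationReason.LENGTH
            break
        p_new = pts[-1] + h * u
        idx = field.grid.containing_voxel(p_new)
        if idx is None:
            reason = TerminationReason.NO_CANDIDATE
            break
        if not field.in_mask(idx):
            reason = TerminationReason.MASK_EXIT
            break
        if not field.passes_fa(idx, params.FA_th):
            reason = TerminationReason.FA
            break
        dirs = field.directions_at(idx)
        if len(dirs) == 0:
            reason = TerminationReason.NO_CANDIDATE
            break
        angles = [axial_angle(u, v) for v, _ in dirs]
        i = int(np.argmin(angles))
        if angles[i] > params.theta_rad:
            reason = TerminationReason.ANGLE
            break
        v = dirs.directions[i]
        if float(np.dot(v, u)) < 0.0:
            v = -v
        pts.append(p_new)
        u = v
        length += h
    return pts, reason


def track_streamline(
    seeds: Sequence[Sequence[int]],
    field: VectorField,
    params: TrackingParams,
    integration_step: float = 0.02,
) -> list[Pathway]:
    """Multidirectional streamline baseline: fixed-step direction following.

    From each seed-voxel axis a polyline is integrated at ``integration_step``
    (mm) both ways, at each step following the nearest-axial-angle direction
    of the voxel under the current point, under the same angle/length/FA/mask
    stop rules as the NURBS trackers.
    """
    pathways: list[Pathway] = []
    for seed in seeds:
        seed = tuple(int(v) for v in seed)
        if (
            not field.grid.in_bounds(seed)
            or not field.in_mask(seed)
            or len(field.directions_at(seed)) == 0
            or not field.passes_fa(seed, params.FA_th)
        ):
            continue
        c = field.grid.voxel_center(seed)
        for v, _ in field.directions_at(seed):
            fwd, reason = _integrate_side(c, v, field, params, integration_step, params.L_th)
            used = integration_step * (len(fwd) - 1)
            bwd, _ = _integrate_side(
                c, -v, field, params, integration_step, max(0.0, params.L_th - used)
            )
            pts = list(reversed(bwd[1:])) + fwd
            if len(pts) < 2:
                continue
            pathways.append(
                Pathway(np.vstack(pts), seed_voxel=seed, termination_reason=reason)
            )
    return pathways
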