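"""Consecutive-direction extraction across 26-connected voxels.

Starting from a seed voxel and a seed axis, the chain grows greedily: at each
step the candidate neighbors are the unvisited 26-neighbors in the forward
hemisphere whose anisotropy clears ``FA_th`` and whose centers lie within
``d_th`` of the line carried by the current direction (the distance test is
what separates this scheme from FACT, which can hop to a diagonal neighbor
whose center is far off the current direction's line).  Among the candidate
(neighbor, direction) pairs within the axial angle threshold, the winner is
the one whose neighbor center the direction line passes closest to — the
most collinear continuation; ties break on smaller axial angle, then larger
diffusion probability, then lexicographic voxel index.

Directions are axial; each accepted direction is flipped to keep a
non-negative dot product with the incoming one so the chain has a consistent
polarity.  Visited voxels are never re-entered (loop prevention).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .grid import (
    TerminationReason,
    TrackingParams,
    VectorField,
    axial_angle,
    point_line_distance,
)

__all__ = ["ChainNode", "DirectionChain", "select_next", "extract_chain", "bidirectional_chains"]

_TIE_TOL = 1e-9


@dataclass
class ChainNode:
    """One voxel on a chain: its index, polarity-aligned axis, and probability."""

    voxel: tuple[int, int, int]
    direction: np.ndarray
    probability: float

    def __post_init__(self) -> None:
        self.voxel = tuple(int(v) for v in self.voxel)
        self.direction = np.asarray(self.direction, dtype=float)
        if abs(np.linalg.norm(self.direction) - 1.0) > 1e-6:
            raise ValueError("node direction must be unit")
        if self.probability <= 0:
            raise ValueError("node probability must be > 0")


@dataclass
class DirectionChain:
    """Ordered consecutive directions along one pathway."""

    nodes: list[ChainNode]
    termination_reason: TerminationReason

    def __len__(self) -> int:
        return len(self.nodes)

    def voxels(self) -> list[tuple[int, int, int]]:
        return [n.voxel for n in self.nodes]

    def center_length(self, field: VectorField) -> float:
        """Cumulative voxel-center-to-center length, mm."""
        centers = [field.grid.voxel_center(n.voxel) for n in self.nodes]
        return float(
            sum(np.linalg.norm(b - a) for a, b in zip(centers[:-1], centers[1:]))
        )

    def to_records(self) -> list[dict]:
        return [
            {
                "voxel": list(n.voxel),
                "direction": [float(x) for x in n.direction],
                "probability": float(n.probability),
            }
            for n in self.nodes
        ]


def _step(
    current: ChainNode,
    field: VectorField,
    params: TrackingParams,
    visited: set[tuple[int, int, int]],
) -> tuple[Optional[ChainNode], TerminationReason]:
    """Best next node, or (None, reason) when no candidate survives."""
    grid = field.grid
    c0 = grid.voxel_center(current.voxel)
    u = current.direction
    d_th = params.distance_threshold(grid)

    saw_forward = False
    saw_mask_fail = False
    saw_fa_fail = False
    saw_near = False
    saw_direction = False
    best: Optional[tuple[float, float, float, tuple[int, int, int], np.ndarray]] = None

    for nb in grid.neighbors26(current.voxel):
        if nb in visited:
            continue
        c = grid.voxel_center(nb)
        if float(np.dot(c - c0, u)) <= 0.0:  # strict forward hemisphere
            continue
        saw_forward = True
        if not field.in_mask(nb):
            saw_mask_fail = True
            continue
        if not field.passes_fa(nb, params.FA_th):
            saw_fa_fail = True
            continue
        perp = point_line_distance(c, c0, u)
        if perp >= d_th:
            continue
        saw_near = True
        for v, d in field.directions_at(nb):
            saw_direction = True
            ang = axial_angle(u, v)
            if ang > params.theta_rad:
                continue
            cand = (perp, ang, d, nb, v)
            if best is None or _better(cand, best):
                best = cand

    if best is not None:
        perp, ang, d, nb, v = best
        if float(np.dot(v, u)) < 0.0:  # keep forward polarity
            v = -v
        return ChainNode(nb, v, d), TerminationReason.NO_CANDIDATE
    if not saw_forward:
        return None, TerminationReason.NO_CANDIDATE
    if saw_direction:
        return None, TerminationReason.ANGLE
    if saw_mask_fail and not saw_fa_fail:
        return None, TerminationReason.MASK_EXIT
    if saw_fa_fail:
        return None, TerminationReason.FA
    return None, TerminationReason.NO_CANDIDATE


def _better(a: tuple, b: tuple) -> bool:
    """Deterministic candidate order: min line distance, min angle, max d, lex index."""
    if a[0] < b[0] - _TIE_TOL:
        return True
    if a[0] > b[0] + _TIE_TOL:
        return False
    if a[1] < b[1] - _TIE_TOL:
        return True
    if a[1] > b[1] + _TIE_TOL:
        return False
    if a[2] > b[2] + _TIE_TOL:
        return True
    if a[2] < b[2] - _TIE_TOL:
        return False
    return a[3] < b[3]


def select_next(
    current: ChainNode,
    field: VectorField,
    params: TrackingParams,
    visited: set[tuple[int, int, int]],
) -> Optional[ChainNode]:
    """The next (neighbor, direction) under the distance/angle/FA constraints."""
    node, _ = _step(current, field, params, visited)
    return node


def _seed_node(
    seed: tuple[int, int, int], seed_direction: np.ndarray, field: VectorField
) -> ChainNode:
    dirs = field.directions_at(seed)
    if len(dirs) == 0:
        raise ValueError(f"seed voxel {seed} holds no diffusion directions")
    u = np.asarray(seed_direction, dtype=float)
    u = u / np.linalg.norm(u)
    # attach the voxel axis closest to the requested launch direction
    angles = [axial_angle(u, v) for v, _ in dirs]
    i = int(np.argmin(angles))
    v = dirs.directions[i]
    if float(np.dot(v, u)) < 0.0:
        v = -v
    return ChainNode(tuple(int(x) for x in seed), v, float(dirs.probabilities[i]))


def extract_chain(
    seed: Sequence[int],
    seed_direction: Sequence[float],
    field: VectorField,
    params: TrackingParams,
    *,
    length_budget: Optional[float] = None,
    visited: Optional[set[tuple[int, int, int]]] = None,
) -> DirectionChain:
    """Grow one chain from ``seed`` along ``seed_direction``.

    Stops when the accumulated center-to-center length would exceed the
    budget (default ``params.L_th``), when no candidate survives the
    constraints, or when anisotropy/mask fails ahead.
    """
    seed = tuple(int(v) for v in seed)
    if not field.grid.in_bounds(seed):
        raise ValueError(f"seed {seed} out of bounds")
    if not field.in_mask(seed):
        raise ValueError(f"seed {seed} outside the white-matter mask")
    if not field.passes_fa(seed, params.FA_th):
        raise ValueError(f"seed {seed} below the FA threshold")
    budget = params.L_th if length_budget is None else float(length_budget)

    node = _seed_node(seed, np.asarray(seed_direction, dtype=float), field)
    nodes = [node]
    vis = visited if visited is not None else set()
    vis.add(seed)
    length = 0.0
    reason = TerminationReason.NO_CANDIDATE
    while True:
        nxt, reason = _step(nodes[-1], field, params, vis)
        if nxt is None:
            break
        step_len = float(
            np.linalg.norm(
                field.grid.voxel_center(nxt.voxel) - field.grid.voxel_center(nodes[-1].voxel)
            )
        )
        if length + step_len > budget:
            reason = TerminationReason.LENGTH
            break
        nodes.append(nxt)
        vis.add(nxt.voxel)
        length += step_len
    return DirectionChain(nodes, reason)


def bidirectional_chains(
    seed: Sequence[int],
    field: VectorField,
    params: TrackingParams,
) -> list[DirectionChain]:
    """One spliced two-sided chain per seed-voxel axis.

    The forward side (along ``+v_i``) runs first under the full length budget;
    the backward side gets the remainder, so the combined center-to-center
    length never exceeds ``L_th``.  The backward half is reversed and its
    directions flipped so the spliced chain carries one consistent polarity
    from its backward end to its forward end.
    """
    seed = tuple(int(v) for v in seed)
    dirs = field.directions_at(seed)
    out: list[DirectionChain] = []
    for v, _ in dirs:
        plus = extract_chain(seed, v, field, params)
        used = plus.center_length(field)
        remaining = max(0.0, params.L_th - used)
        minus = extract_chain(
            seed,
            -v,
            field,
            params,
            length_budget=remaining,
            visited={n.voxel for n in plus.nodes},
        )
        tail = [
            ChainNode(n.voxel, -n.direction, n.probability)
            for n in reversed(minus.nodes[1:])
        ]
        out.append(DirectionChain(tail + plus.nodes, plus.termination_reason))
    return out
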