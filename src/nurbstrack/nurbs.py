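"""Rational B-spline (NURBS) curve machinery.

A degree-``p`` NURBS curve is defined by control points ``P_i``, strictly
positive weights ``w_i`` and a clamped knot vector normalized to [0, 1]:

    C(u) = sum_i N_{i,p}(u) w_i P_i / sum_i N_{i,p}(u) w_i

where ``N_{i,p}`` are the B-spline basis functions (Cox-de Boor recursion).
Clamping (end knots repeated ``p + 1`` times) forces the curve to interpolate
the first and last control points; the number of control points must be at
least the order ``p + 1``.  Cubic curves are the workhorse here — higher
orders buy little and cost conditioning.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .grid import Pathway

__all__ = [
    "NurbsCurve",
    "make_knot_vector",
    "basis_functions",
    "evaluate",
    "evaluate_many",
    "curve_tangent",
    "sample_pathway",
]


def make_knot_vector(n_ctrl: int, degree: int) -> np.ndarray:
    """Clamped, normalized knot vector with evenly distributed interior knots.

    ``degree + 1`` zeros, ``n_ctrl - degree - 1`` uniform interior knots in
    (0, 1), ``degree + 1`` ones; total length ``n_ctrl + degree + 1``.
    """
    if degree < 1:
        raise ValueError("degree must be >= 1")
    if n_ctrl < degree + 1:
        raise ValueError(
            f"need at least order = degree + 1 = {degree + 1} control points, got {n_ctrl}"
        )
    n_interior = n_ctrl - degree - 1
    interior = np.arange(1, n_interior + 1, dtype=float) / (n_interior + 1)
    return np.concatenate([np.zeros(degree + 1), interior, np.ones(degree + 1)])


def _find_span(knots: np.ndarray, degree: int, u: float, n_ctrl: int) -> int:
    # right-continuous at interior knots; u == 1 falls in the last span
    if u >= knots[n_ctrl]:
        return n_ctrl - 1
    return int(np.searchsorted(knots, u, side="right")) - 1


def basis_functions(knots: np.ndarray, degree: int, u: float) -> np.ndarray:
    """All ``n_ctrl`` B-spline basis values at parameter ``u`` in [0, 1].

    At most ``degree + 1`` entries are nonzero; the values are non-negative
    and sum to 1 (partition of unity).
    """
    knots = np.asarray(knots, dtype=float)
    n_ctrl = len(knots) - degree - 1
    if not 0.0 <= u <= 1.0:
        raise ValueError(f"parameter u={u} outside [0, 1]")
    span = _find_span(knots, degree, u, n_ctrl)
    # banded Cox-de Boor triangle (The NURBS Book, A2.2)
    N = np.zeros(degree + 1)
    N[0] = 1.0
    left = np.zeros(degree + 1)
    right = np.zeros(degree + 1)
    for j in range(1, degree + 1):
        left[j] = u - knots[span + 1 - j]
        right[j] = knots[span + j] - u
        saved = 0.0
        for r in range(j):
            temp = N[r] / (right[r + 1] + left[j - r])
            N[r] = saved + right[r + 1] * temp
            saved = left[j - r] * temp
        N[j] = saved
    full = np.zeros(n_ctrl)
    full[span - degree : span + 1] = N
    return full


@dataclass
class NurbsCurve:
    """A clamped rational B-spline curve in 3-D mm space."""

    degree: int
    control_points: np.ndarray
    weights: np.ndarray
    knots: np.ndarray

    def __post_init__(self) -> None:
        self.control_points = np.atleast_2d(np.asarray(self.control_points, dtype=float))
        self.weights = np.atleast_1d(np.asarray(self.weights, dtype=float))
        self.knots = np.asarray(self.knots, dtype=float)
        n_ctrl = self.control_points.shape[0]
        p = self.degree
        if self.control_points.shape[1] != 3:
            raise ValueError("control points must be (n+1) x 3")
        if n_ctrl < p + 1:
            raise ValueError("control-point count must be >= order (degree + 1)")
        if self.weights.shape != (n_ctrl,) or np.any(self.weights <= 0):
            raise ValueError("weights must be positive, one per control point")
        if len(self.knots) != n_ctrl + p + 1:
            raise ValueError("knot vector length must be n_ctrl + degree + 1")
        if np.any(np.diff(self.knots) < 0):
            raise ValueError("knots must be nondecreasing")
        if not (
            np.allclose(self.knots[: p + 1], 0.0)
            and np.allclose(self.knots[-(p + 1) :], 1.0)
        ):
            raise ValueError("knot vector must be clamped and normalized to [0, 1]")

    @property
    def n_ctrl(self) -> int:
        return self.control_points.shape[0]

    def __call__(self, u: float) -> np.ndarray:
        return evaluate(self, u)


def evaluate(curve: NurbsCurve, u: float) -> np.ndarray:
    """Point on the curve: rational combination of control points at ``u``."""
    N = basis_functions(curve.knots, curve.degree, float(u))
    Nw = N * curve.weights
    denom = Nw.sum()
    if denom <= 0:  # unreachable under the class invariants
        raise ArithmeticError("zero rational weight sum")
    return Nw @ curve.control_points / denom


def evaluate_many(curve: NurbsCurve, us: Sequence[float]) -> np.ndarray:
    """Evaluate at many parameters; rows follow the input order."""
    return np.array([evaluate(curve, u) for u in np.asarray(us, dtype=float)])


def curve_tangent(curve: NurbsCurve, u: float, h: float = 1e-6) -> np.ndarray:
    """Unit tangent by a central finite difference (one-sided at the ends)."""
    a, b = max(0.0, u - h), min(1.0, u + h)
    d = evaluate(curve, b) - evaluate(curve, a)
    n = np.linalg.norm(d)
    if n == 0:
        raise ArithmeticError("degenerate tangent")
    return d / n


def _dense_polyline(curve: NurbsCurve, tol: float) -> tuple[np.ndarray, np.ndarray]:
    """Parameters and points sampled densely enough that chord length is stable.

    Doubles the sample count until the total chord length changes by less
    than ``tol`` between refinements.
    """
    k = 64
    us = np.linspace(0.0, 1.0, k + 1)
    pts = evaluate_many(curve, us)
    total = float(np.sum(np.linalg.norm(np.diff(pts, axis=0), axis=1)))
    while k < 2**14:
        k *= 2
        us = np.linspace(0.0, 1.0, k + 1)
        pts = evaluate_many(curve, us)
        new_total = float(np.sum(np.linalg.norm(np.diff(pts, axis=0), axis=1)))
        if abs(new_total - total) < tol:
            total = new_total
            break
        total = new_total
    return us, pts


def sample_pathway(
    curve: NurbsCurve,
    step: float,
    *,
    seed_voxel: Optional[tuple[int, int, int]] = None,
    termination_reason=None,
) -> Pathway:
    """Discretize the curve into points near-equally spaced in arc length.

    Chord-length reparameterization: the curve is sampled densely (adaptive
    refinement, tolerance ``1e-4 * step``), cumulative chord length is
    inverted at multiples of the requested step, and the exact curve
    endpoints are pinned.  A step longer than the curve yields just the two
    endpoints; a fully degenerate curve (all control points coincident)
    yields its single point twice, with a warning.
    """
    if step <= 0:
        raise ValueError("step must be > 0")
    span = np.ptp(curve.control_points, axis=0)
    if float(np.max(span)) == 0.0:
        warnings.warn("degenerate curve: all control points coincide", stacklevel=2)
        p = curve.control_points[0]
        return Pathway(
            np.vstack([p, p]), seed_voxel=seed_voxel, termination_reason=termination_reason
        )
    us, pts = _dense_polyline(curve, tol=1e-4 * step)
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    total = float(cum[-1])
    n_pts = max(2, int(round(total / step)) + 1)
    targets = np.linspace(0.0, total, n_pts)
    u_targets = np.interp(targets, cum, us)
    out = evaluate_many(curve, u_targets)
    out[0] = evaluate(curve, 0.0)
    out[-1] = evaluate(curve, 1.0)
    return Pathway(out, seed_voxel=seed_voxel, termination_reason=termination_reason)
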