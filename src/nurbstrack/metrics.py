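"""Tractogram evaluation: local symmetric-RMSE metrics and global connectivity.

Local metrics compare an estimated pathway to a ground-truth pathway
point-to-polyline, symmetrically (mean of the two directed mean squared
errors, then square root):

* spatial metric  — L2 distance to the closest point on the other polyline, mm;
* tangent metric  — axial angle between finite-difference unit tangents at
  matched closest points, radians;
* curve metric    — absolute difference of discrete curvatures (circumscribed
  circle of consecutive point triples) at matched closest points, 1/mm.

Global metrics classify each pathway against bundle endpoint ROIs:
valid connection (both endpoints in the two ROIs of one bundle, path inside
the white-matter mask), invalid connection (endpoints in ROIs of different
bundles), otherwise no connection; VB/IB count the distinct bundles / wrong
ROI pairs so reached.  The three classes partition the pathway set, so
VC + IC + NC = 100%.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .grid import Pathway, VoxelGrid

__all__ = [
    "BundleTruth",
    "MetricReport",
    "spatial_metric",
    "tangent_metric",
    "curve_metric",
    "connectivity_metrics",
]


@dataclass
class BundleTruth:
    """Ground-truth bundles: analytic pathways, endpoint ROI masks, WM mask."""

    grid: VoxelGrid
    curves: list[Pathway]
    endpoint_rois: list[tuple[np.ndarray, np.ndarray]]  # per bundle: (mask_a, mask_b)
    wm_mask: np.ndarray

    def __post_init__(self) -> None:
        self.wm_mask = np.asarray(self.wm_mask, dtype=bool)
        if len(self.curves) != len(self.endpoint_rois):
            raise ValueError("one ROI pair per ground-truth bundle required")
        for a, b in self.endpoint_rois:
            if a.shape != tuple(self.grid.dims) or b.shape != tuple(self.grid.dims):
                raise ValueError("ROI mask shapes must match the grid")


@dataclass
class MetricReport:
    """Connectivity percentages/counts, optionally with local metric values."""

    vc: float
    ic: float
    nc: float
    vb: int
    ib: int
    labels: list[str] = field(default_factory=list)
    sm: Optional[float] = None
    tm: Optional[float] = None
    cm: Optional[float] = None

    def to_dict(self) -> dict:
        out = {"vc": self.vc, "ic": self.ic, "nc": self.nc, "vb": self.vb, "ib": self.ib}
        for k in ("sm", "tm", "cm"):
            v = getattr(self, k)
            if v is not None:
                out[k] = v
        return out


def _closest_on_polyline(points: np.ndarray, poly: np.ndarray):
    """Closest point on ``poly`` for each of ``points``.

    Returns (distances, closest points, nearest-vertex indices); vectorized
    point-to-segment projection over all segments.
    """
    a = poly[:-1]  # (S, 3)
    d = poly[1:] - a
    seg_len2 = np.einsum("ij,ij->i", d, d)
    seg_len2 = np.where(seg_len2 == 0, 1.0, seg_len2)
    # (P, S) parameter of the projection, clamped to the segment
    t = np.einsum("pk,sk->ps", points, d)
    t = (t - np.einsum("sk,sk->s", a, d)) / seg_len2
    t = np.clip(t, 0.0, 1.0)
    proj = a[None, :, :] + t[:, :, None] * d[None, :, :]  # (P, S, 3)
    diff = points[:, None, :] - proj
    dist2 = np.einsum("psk,psk->ps", diff, diff)
    seg_idx = np.argmin(dist2, axis=1)
    rows = np.arange(points.shape[0])
    # index of the polyline vertex nearest the closest point
    vert_idx = seg_idx + (t[rows, seg_idx] > 0.5).astype(int)
    return np.sqrt(dist2[rows, seg_idx]), proj[rows, seg_idx], vert_idx


def _polyline_tangents(points: np.ndarray) -> np.ndarray:
    """Unit tangent at each vertex (central differences, one-sided at ends)."""
    g = np.gradient(points, axis=0)
    n = np.linalg.norm(g, axis=1, keepdims=True)
    n = np.where(n == 0, 1.0, n)
    return g / n


def _discrete_curvature(points: np.ndarray) -> np.ndarray:
    """Curvature (1/mm) at each vertex via the circumscribed circle of triples.

    Endpoints copy their interior neighbor's value; collinear triples have
    zero curvature.
    """
    p0, p1, p2 = points[:-2], points[1:-1], points[2:]
    a = np.linalg.norm(p1 - p0, axis=1)
    b = np.linalg.norm(p2 - p1, axis=1)
    c = np.linalg.norm(p2 - p0, axis=1)
    cross = np.cross(p1 - p0, p2 - p0)
    area2 = np.linalg.norm(cross, axis=1)  # = 2 * triangle area
    denom = a * b * c
    kappa = np.where(denom > 0, 2.0 * area2 / np.where(denom > 0, denom, 1.0), 0.0)
    return np.concatenate([[kappa[0]], kappa, [kappa[-1]]])


def _check_pathways(est: Pathway, truth: Pathway, min_pts: int) -> None:
    if len(est) < min_pts or len(truth) < min_pts:
        raise ValueError(f"both pathways need at least {min_pts} points")


def _symmetric_rmse(sq_a: np.ndarray, sq_b: np.ndarray) -> float:
    return float(np.sqrt(0.5 * (np.mean(sq_a) + np.mean(sq_b))))


def spatial_metric(estimated: Pathway, truth: Pathway) -> float:
    """Symmetric RMSE of closest-point L2 distances, mm."""
    _check_pathways(estimated, truth, 2)
    d_et, _, _ = _closest_on_polyline(estimated.points, truth.points)
    d_te, _, _ = _closest_on_polyline(truth.points, estimated.points)
    return _symmetric_rmse(d_et**2, d_te**2)


def _directed_tangent_sq(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    ta = _polyline_tangents(a)
    tb = _polyline_tangents(b)
    _, _, vert_idx = _closest_on_polyline(a, b)
    cosang = np.abs(np.einsum("ij,ij->i", ta, tb[vert_idx]))
    ang = np.arccos(np.clip(cosang, 0.0, 1.0))
    return ang**2


def tangent_metric(estimated: Pathway, truth: Pathway) -> float:
    """Symmetric RMSE of axial tangent angles at matched points, radians."""
    _check_pathways(estimated, truth, 3)
    return _symmetric_rmse(
        _directed_tangent_sq(estimated.points, truth.points),
        _directed_tangent_sq(truth.points, estimated.points),
    )


def _directed_curvature_sq(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    ka = _discrete_curvature(a)
    kb = _discrete_curvature(b)
    _, _, vert_idx = _closest_on_polyline(a, b)
    return (np.abs(ka - kb[vert_idx])) ** 2


def curve_metric(estimated: Pathway, truth: Pathway) -> float:
    """Symmetric RMSE of absolute discrete-curvature differences, 1/mm."""
    _check_pathways(estimated, truth, 5)
    return _symmetric_rmse(
        _directed_curvature_sq(estimated.points, truth.points),
        _directed_curvature_sq(truth.points, estimated.points),
    )


def _endpoint_roi(
    point: np.ndarray, truth: BundleTruth
) -> Optional[tuple[int, int]]:
    """(bundle index, end index) of the ROI containing ``point``'s voxel."""
    idx = truth.grid.containing_voxel(point)
    if idx is None:
        return None
    for b, (roi_a, roi_b) in enumerate(truth.endpoint_rois):
        if roi_a[idx]:
            return (b, 0)
        if roi_b[idx]:
            return (b, 1)
    return None


def _inside_mask(pathway: Pathway, truth: BundleTruth) -> bool:
    for p in pathway.points:
        idx = truth.grid.containing_voxel(p)
        if idx is None or not truth.wm_mask[idx]:
            return False
    return True


def classify_pathway(pathway: Pathway, truth: BundleTruth) -> tuple[str, Optional[tuple]]:
    """('vc', bundle), ('ic', roi-pair) or ('nc', None) for one pathway."""
    r0 = _endpoint_roi(pathway.points[0], truth)
    r1 = _endpoint_roi(pathway.points[-1], truth)
    if r0 is not None and r1 is not None:
        if r0[0] == r1[0] and r0[1] != r1[1]:
            if _inside_mask(pathway, truth):
                return "vc", (r0[0],)
            return "nc", None
        if r0 != r1:
            return "ic", tuple(sorted((r0, r1)))
    return "nc", None


def connectivity_metrics(pathways: Sequence[Pathway], truth: BundleTruth) -> MetricReport:
    """Classify every pathway and summarize VC/IC/NC (%) and VB/IB (counts)."""
    # ROI disjointness is a precondition for unambiguous endpoint assignment
    flat = [m for pair in truth.endpoint_rois for m in pair]
    total = np.zeros(tuple(truth.grid.dims), dtype=int)
    for m in flat:
        total += m.astype(int)
    if np.any(total > 1):
        raise ValueError("endpoint ROIs must be pairwise disjoint")

    if not pathways:
        return MetricReport(0.0, 0.0, 0.0, 0, 0, [])
    labels: list[str] = []
    valid_bundles: set[int] = set()
    invalid_pairs: set[tuple] = set()
    counts = {"vc": 0, "ic": 0, "nc": 0}
    for pw in pathways:
        label, detail = classify_pathway(pw, truth)
        labels.append(label)
        counts[label] += 1
        if label == "vc":
            valid_bundles.add(detail[0])
        elif label == "ic":
            invalid_pairs.add(detail)
    n = len(pathways)
    return MetricReport(
        vc=100.0 * counts["vc"] / n,
        ic=100.0 * counts["ic"] / n,
        nc=100.0 * counts["nc"] / n,
        vb=len(valid_bundles),
        ib=len(invalid_pairs),
        labels=labels,
    )
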