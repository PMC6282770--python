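import math

import numpy as np
import pytest

from nurbstrack.grid import Pathway, VoxelGrid
from nurbstrack.metrics import (
    BundleTruth,
    connectivity_metrics,
    curve_metric,
    spatial_metric,
    tangent_metric,
)


def line(p0, p1, n=60):
    return Pathway(np.linspace(p0, p1, n))


def circle(r, n=400, half=True):
    th = np.linspace(0, np.pi if half else 2 * np.pi, n)
    return Pathway(np.column_stack([r * np.cos(th), r * np.sin(th), np.zeros(n)]))


def test_local_metrics_zero_on_identical_curves():
    rng = np.random.default_rng(1)
    pts = np.cumsum(rng.uniform(0.2, 1.0, (30, 3)), axis=0)
    pw = Pathway(pts)
    assert spatial_metric(pw, pw) == 0.0
    assert tangent_metric(pw, pw) == pytest.approx(0.0, abs=1e-7)
    assert curve_metric(pw, pw) == 0.0


def test_spatial_metric_equals_offset_for_parallel_segments():
    a = line((0, 0, 0), (10, 0, 0))
    b = line((0, 1, 0), (10, 1, 0))
    assert spatial_metric(a, b) == pytest.approx(1.0, abs=1e-12)


def test_spatial_metric_symmetric_and_translation_equivariant():
    rng = np.random.default_rng(2)
    a = Pathway(np.cumsum(rng.uniform(0.2, 1.0, (25, 3)), axis=0))
    b = Pathway(np.cumsum(rng.uniform(0.2, 1.0, (19, 3)), axis=0))
    assert spatial_metric(a, b) == pytest.approx(spatial_metric(b, a))
    # perpendicular offset of a shared straight direction -> exactly the offset
    s = line((0, 0, 0), (10, 0, 0))
    s_off = Pathway(s.points + [0, 0.37, 0])
    assert spatial_metric(s, s_off) == pytest.approx(0.37, abs=1e-12)


def test_spatial_metric_matches_dense_bruteforce():
    rng = np.random.default_rng(3)
    a = Pathway(np.cumsum(rng.uniform(0.1, 0.8, (12, 3)), axis=0))
    b = Pathway(np.cumsum(rng.uniform(0.1, 0.8, (15, 3)), axis=0))

    def dense_min_dist(points, poly, k=2000):
        # dense sampling of every segment of the target polyline
        seg_pts = np.concatenate(
            [np.linspace(p, q, k) for p, q in zip(poly[:-1], poly[1:])]
        )
        return np.array(
            [np.min(np.linalg.norm(seg_pts - p, axis=1)) for p in points]
        )

    mse_ab = np.mean(dense_min_dist(a.points, b.points) ** 2)
    mse_ba = np.mean(dense_min_dist(b.points, a.points) ** 2)
    expected = math.sqrt(0.5 * (mse_ab + mse_ba))
    assert spatial_metric(a, b) == pytest.approx(expected, rel=0.01)


def test_tangent_metric_constant_angle():
    # two long straight segments crossing at 30 degrees through the origin;
    # matched closest points lie along the overlap, angle constant = pi/6
    a = line((-10, 0, 0), (10, 0, 0), n=200)
    c, s = math.cos(math.radians(30)), math.sin(math.radians(30))
    b = Pathway(np.linspace((-10 * c, -10 * s, 0), (10 * c, 10 * s, 0), 200))
    assert tangent_metric(a, b) == pytest.approx(math.pi / 6, rel=0.02)


def test_tangent_metric_orientation_free():
    a = line((0, 0, 0), (10, 0, 0))
    b = Pathway(a.points[::-1].copy())
    assert tangent_metric(a, b) == pytest.approx(0.0, abs=1e-12)


def test_curve_metric_straight_lines_zero():
    assert curve_metric(line((0, 0, 0), (10, 0, 0)), line((0, 1, 0), (9, 1, 0))) == 0.0


def test_curve_metric_circle_vs_line():
    est = circle(10.0)
    truth = line((-10, 0, 0), (10, 0, 0), n=200)
    assert curve_metric(est, truth) == pytest.approx(0.1, rel=0.01)


def test_curve_metric_identical_circles():
    assert curve_metric(circle(5.0), circle(5.0)) == pytest.approx(0.0, abs=1e-9)


def test_metric_preconditions():
    a = line((0, 0, 0), (1, 0, 0), n=2)
    with pytest.raises(ValueError):
        tangent_metric(a, a)
    with pytest.raises(ValueError):
        curve_metric(a, a)


def toy_truth():
    grid = VoxelGrid((10, 10, 3))
    dims = (10, 10, 3)
    r1a, r1b, r2a, r2b = (np.zeros(dims, dtype=bool) for _ in range(4))
    r1a[0:2, 0:2, :] = True   # bundle 1 end A
    r1b[8:10, 0:2, :] = True  # bundle 1 end B
    r2a[0:2, 8:10, :] = True  # bundle 2 end A
    r2b[8:10, 8:10, :] = True # bundle 2 end B
    wm = np.ones(dims, dtype=bool)
    curves = [
        Pathway(np.linspace((1, 1, 1.5), (9, 1, 1.5), 20)),
        Pathway(np.linspace((1, 9, 1.5), (9, 9, 1.5), 20)),
    ]
    return BundleTruth(grid, curves, [(r1a, r1b), (r2a, r2b)], wm)


def test_connectivity_three_pathway_toy():
    truth = toy_truth()
    valid = Pathway(np.linspace((1, 1, 1.5), (9, 1, 1.5), 20))       # bundle 1 A->B
    invalid = Pathway(np.linspace((1, 1, 1.5), (9, 9, 1.5), 20))     # bundle1 A -> bundle2 B
    dangling = Pathway(np.linspace((4, 4, 1.5), (6, 6, 1.5), 20))    # ends mid-mask
    report = connectivity_metrics([valid, invalid, dangling], truth)
    assert report.vc == pytest.approx(100 / 3)
    assert report.ic == pytest.approx(100 / 3)
    assert report.nc == pytest.approx(100 / 3)
    assert report.vb == 1 and report.ib == 1
    assert report.labels == ["vc", "ic", "nc"]


def test_connectivity_all_valid_single_bundle():
    truth = toy_truth()
    pws = [Pathway(np.linspace((1, 1, 1.5), (9, 1, 1.5), 20)) for _ in range(5)]
    report = connectivity_metrics(pws, truth)
    assert report.vc == 100.0 and report.ic == 0.0 and report.nc == 0.0
    assert report.vb == 1 and report.ib == 0


def test_connectivity_empty_list():
    report = connectivity_metrics([], toy_truth())
    assert (report.vc, report.ic, report.nc, report.vb, report.ib) == (0, 0, 0, 0, 0)


def test_connectivity_mask_exit_demotes_to_nc():
    truth = toy_truth()
    truth.wm_mask[5, 0:2, :] = False  # cut bundle 1 mid-way
    pw = Pathway(np.linspace((1, 1, 1.5), (9, 1, 1.5), 40))
    report = connectivity_metrics([pw], truth)
    assert report.labels == ["nc"]


def test_connectivity_rejects_overlapping_rois():
    truth = toy_truth()
    truth.endpoint_rois[1][0][0:2, 0:2, :] = True  # overlap with bundle 1 ROI A
    with pytest.raises(ValueError):
        connectivity_metrics([], truth)


def test_connectivity_matches_independent_classification():
    """Cross-check against a from-scratch classifier on random pathways."""
    truth = toy_truth()
    rng = np.random.default_rng(9)
    pws = []
    for _ in range(40):
        p0 = rng.uniform((0.5, 0.5, 1), (9.5, 9.5, 2))
        p1 = rng.uniform((0.5, 0.5, 1), (9.5, 9.5, 2))
        pws.append(Pathway(np.linspace(p0, p1, 30)))

    def roi_of(p):
        idx = tuple(int(np.floor(c)) for c in p)
        if not all(0 <= i < d for i, d in zip(idx, truth.grid.dims)):
            return None
        for b, pair in enumerate(truth.endpoint_rois):
            for e, mask in enumerate(pair):
                if mask[idx]:
                    return (b, e)
        return None

    expected = []
    for pw in pws:
        r0, r1 = roi_of(pw.points[0]), roi_of(pw.points[-1])
        if r0 and r1 and r0[0] == r1[0] and r0[1] != r1[1]:
            expected.append("vc")
        elif r0 and r1 and r0 != r1:
            expected.append("ic")
        else:
            expected.append("nc")
    report = connectivity_metrics(pws, truth)
    assert report.labels == expected
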