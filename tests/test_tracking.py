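import math

import numpy as np
import pytest

from nurbstrack.chains import bidirectional_chains, extract_chain
from nurbstrack.grid import TrackingParams, VoxelGrid
from nurbstrack.nurbs import curve_tangent
from nurbstrack.phantom import PhantomSpec, generate_field
from nurbstrack.tracking import (
    control_points_G,
    control_points_T,
    convert_weights,
    curve_from_chain,
    track,
    track_streamline,
    voxel_line_intersections,
)
from nurbstrack.metrics import _closest_on_polyline, classify_pathway

from conftest import uniform_field
from _oracles import bruteforce_box_line


@pytest.mark.parametrize(
    "direction, entry, exit_",
    [
        ((1, 0, 0), (0, 0.5, 0.5), (1, 0.5, 0.5)),
        ((1, 1, 1), (0, 0, 0), (1, 1, 1)),
        ((2, 1, 0), (0, 0.25, 0.5), (1, 0.75, 0.5)),
    ],
)
def test_voxel_line_intersections_cases(direction, entry, exit_):
    grid = VoxelGrid((3, 3, 3))
    u = np.asarray(direction, dtype=float)
    u /= np.linalg.norm(u)
    e, x = voxel_line_intersections(grid, (0, 0, 0), u)
    assert np.allclose(e, entry, atol=1e-12)
    assert np.allclose(x, exit_, atol=1e-12)


def test_voxel_line_intersections_match_bruteforce():
    rng = np.random.default_rng(17)
    for _ in range(500):
        dims = tuple(int(rng.integers(1, 6)) for _ in range(3))
        sizes = tuple(float(rng.uniform(0.5, 3.0)) for _ in range(3))
        origin = tuple(float(rng.uniform(-5, 5)) for _ in range(3))
        grid = VoxelGrid(dims, sizes, origin)
        vox = tuple(int(rng.integers(0, d)) for d in dims)
        u = rng.standard_normal(3)
        u /= np.linalg.norm(u)
        e, x = voxel_line_intersections(grid, vox, u)
        lo, hi = grid.voxel_bounds(vox)
        be, bx = bruteforce_box_line(lo, hi, grid.voxel_center(vox), u)
        assert np.allclose(e, be, atol=1e-9)
        assert np.allclose(x, bx, atol=1e-9)


def one_node_chain(field, params):
    return extract_chain(
        (2, 2, 2), field.directions_at((2, 2, 2)).directions[0], field,
        TrackingParams(L_th=0.5),
    )


def test_control_points_single_node():
    field = uniform_field(dims=(5, 5, 5))
    params = TrackingParams()
    chain = one_node_chain(field, params)
    assert len(chain) == 1
    seq_t = control_points_T(chain, field.grid)
    seq_g = control_points_G(chain, field.grid)
    assert len(seq_t) == 3 and len(seq_g) == 2
    assert seq_t.provenance == ["entry", "center", "exit"]
    # collinear along the node direction
    d = seq_t.points[2] - seq_t.points[0]
    assert np.allclose(np.cross(d, chain.nodes[0].direction), 0, atol=1e-12)


def test_two_node_collinear_counts_after_merge(params):
    field = uniform_field(dims=(5, 3, 3))
    chain = extract_chain((1, 1, 1), (1.0, 0, 0), field, TrackingParams(L_th=1.5))
    assert len(chain) == 2
    assert len(control_points_T(chain, field.grid)) == 5
    assert len(control_points_G(chain, field.grid)) == 3


def test_g_points_are_t_points_without_centers(params):
    field = uniform_field()
    chain = bidirectional_chains((10, 10, 10), field, params)[0]
    seq_t = control_points_T(chain, field.grid)
    seq_g = control_points_G(chain, field.grid)
    t_non_centers = seq_t.points[[p != "center" for p in seq_t.provenance]]
    assert np.allclose(t_non_centers, seq_g.points)


def test_collinear_triples_in_every_mode_T(params):
    spec = PhantomSpec(kind="arc")
    field, _ = generate_field(spec)
    seed = next(iter(field.sets))
    chain = bidirectional_chains(seed, field, params)[0]
    seq = control_points_T(chain, field.grid)
    for k, node in enumerate(chain.nodes):
        center = field.grid.voxel_center(node.voxel)
        matches = [
            i for i, (tag, src) in enumerate(zip(seq.provenance, seq.sources))
            if tag == "center" and src == (k,)
        ]
        assert len(matches) == 1
        assert np.allclose(seq.points[matches[0]], center)


def test_convert_weights_rule():
    field = uniform_field(dims=(5, 3, 3))
    chain = extract_chain((1, 1, 1), (1.0, 0, 0), field, TrackingParams(L_th=1.5))
    chain.nodes[0].probability = 0.2
    chain.nodes[1].probability = 0.6
    seq = control_points_G(chain, field.grid)
    w = convert_weights(chain, seq)
    assert w.max() == 1.0
    assert np.allclose(w, [0.2 / 0.6, (0.4) / 0.6, 1.0])


def test_convert_weights_single_node_all_ones(params):
    field = uniform_field(dims=(5, 5, 5))
    chain = one_node_chain(field, params)
    seq = control_points_T(chain, field.grid)
    assert np.allclose(convert_weights(chain, seq), 1.0)


def test_track_straight_phantom_max_deviation(params):
    field, truth = generate_field(PhantomSpec(kind="straight"))
    for mode in ("nurbs_t", "nurbs_g"):
        pws = track([(10, 10, 10)], field, TrackingParams(mode=mode))
        assert len(pws) == 1
        d, _, _ = _closest_on_polyline(pws[0].points, truth.curves[0].points)
        assert d.max() < 0.1


def test_track_crossing_seed_yields_two_pathways(params):
    field, truth = generate_field(PhantomSpec(kind="crossing"))
    center = field.grid.containing_voxel(truth.curves[0].points[len(truth.curves[0]) // 2])
    # the central voxel carries both axes
    assert len(field.directions_at((10, 10, 10))) == 2
    pws = track([(10, 10, 10)], field, params)
    assert len(pws) == 2


def test_track_empty_seed_list(params):
    field, _ = generate_field(PhantomSpec(kind="straight"))
    assert track([], field, params) == []


def test_nurbs_t_tangent_follows_diffusion_direction(params):
    """At the parameter nearest each voxel center the NURBS-T curve tangent
    stays within 15 degrees of the voxel's diffusion axis (smooth chain)."""
    field, _ = generate_field(PhantomSpec(kind="arc"))
    seed = (10, 10, 10)
    chain = bidirectional_chains(seed, field, params)[0]
    curve = curve_from_chain(chain, field.grid, "nurbs_t")
    us = np.linspace(0, 1, 400)
    pts = np.array([curve(u) for u in us])
    for node in chain.nodes:
        c = field.grid.voxel_center(node.voxel)
        i = int(np.argmin(np.linalg.norm(pts - c, axis=1)))
        t = curve_tangent(curve, us[i])
        ang = math.degrees(math.acos(min(1.0, abs(float(np.dot(t, node.direction))))))
        assert ang < 15.0


def test_modes_coincide_on_straight_chain(params):
    field, _ = generate_field(PhantomSpec(kind="straight"))
    pw_t = track([(10, 10, 10)], field, TrackingParams(mode="nurbs_t"))[0]
    pw_g = track([(10, 10, 10)], field, TrackingParams(mode="nurbs_g"))[0]
    d, _, _ = _closest_on_polyline(pw_t.points, pw_g.points)
    assert d.max() < 1e-9


def test_pathway_stays_near_center_polyline(params):
    field, _ = generate_field(PhantomSpec(kind="arc"))
    for mode in ("nurbs_t", "nurbs_g"):
        pws = track([(10, 10, 10)], field, TrackingParams(mode=mode))
        chain = bidirectional_chains((10, 10, 10), field, params)[0]
        centers = np.array([field.grid.voxel_center(n.voxel) for n in chain.nodes])
        d, _, _ = _closest_on_polyline(pws[0].points, centers)
        assert d.max() <= field.grid.diagonal


def test_streamline_straight_and_crossing(params):
    field, truth = generate_field(PhantomSpec(kind="straight"))
    pws = track_streamline([(10, 10, 10)], field, params)
    assert len(pws) == 1
    d, _, _ = _closest_on_polyline(pws[0].points, truth.curves[0].points)
    assert d.max() < 0.75  # discrete integration near the tube axis

    field_x, truth_x = generate_field(PhantomSpec(kind="crossing"))
    pws = track_streamline([(10, 10, 10)], field_x, params)
    assert len(pws) == 2
    for pw in pws:
        label, _ = classify_pathway(pw, truth_x)
        assert label == "vc"
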