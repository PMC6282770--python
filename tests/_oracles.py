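"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately naive (direct definitions, exhaustive
enumeration) and shares no code with the package internals it checks.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


def bruteforce_neighbors(dims, idx):
    """All in-bounds voxels of the 3x3x3 block around idx, minus idx."""
    out = []
    for d in itertools.product((-1, 0, 1), repeat=3):
        if d == (0, 0, 0):
            continue
        n = tuple(i + o for i, o in zip(idx, d))
        if all(0 <= v < s for v, s in zip(n, dims)):
            out.append(n)
    return out


def min_distance_to_line(p, a, u, n_grid=200001):
    """Distance from p to the line a + t*u by dense numeric minimization."""
    p, a, u = (np.asarray(x, dtype=float) for x in (p, a, u))
    t = np.linspace(-100, 100, n_grid)
    pts = a[None, :] + t[:, None] * u[None, :]
    d = np.linalg.norm(pts - p[None, :], axis=1)
    i = int(np.argmin(d))
    # golden-section polish on the bracketing interval
    lo, hi = t[max(0, i - 1)], t[min(n_grid - 1, i + 1)]
    from scipy.optimize import minimize_scalar

    res = minimize_scalar(
        lambda tt: float(np.linalg.norm(a + tt * u - p)), bounds=(lo, hi), method="bounded"
    )
    return float(res.fun)


def bruteforce_box_line(lo, hi, c, u):
    """Line through c along u vs. the box [lo, hi]: intersect all six facet
    planes, keep points lying within their facet, order by parameter."""
    lo, hi, c, u = (np.asarray(x, dtype=float) for x in (lo, hi, c, u))
    hits = []
    for ax in range(3):
        if u[ax] == 0:
            continue
        for plane in (lo[ax], hi[ax]):
            t = (plane - c[ax]) / u[ax]
            p = c + t * u
            ok = True
            for other in range(3):
                if other == ax:
                    continue
                if not (lo[other] - 1e-12 <= p[other] <= hi[other] + 1e-12):
                    ok = False
            if ok:
                hits.append((t, p))
    hits.sort(key=lambda h: h[0])
    return hits[0][1], hits[-1][1]


def deboor_basis(knots, degree, i, u):
    """Cox-de Boor recursion straight from the definition (0/0 := 0)."""
    if degree == 0:
        return 1.0 if knots[i] <= u < knots[i + 1] else 0.0
    left = 0.0
    den = knots[i + degree] - knots[i]
    if den > 0:
        left = (u - knots[i]) / den * deboor_basis(knots, degree - 1, i, u)
    right = 0.0
    den = knots[i + degree + 1] - knots[i + 1]
    if den > 0:
        right = (knots[i + degree + 1] - u) / den * deboor_basis(knots, degree - 1, i + 1, u)
    return left + right


def deboor_point(knots, degree, ctrl, u):
    """Non-rational B-spline point by the naive recursion (u < 1)."""
    ctrl = np.asarray(ctrl, dtype=float)
    n = ctrl.shape[0]
    coeff = np.array([deboor_basis(knots, degree, i, u) for i in range(n)])
    return coeff @ ctrl


def axial_angle_deg(u, v):
    return math.degrees(math.acos(min(1.0, abs(float(np.dot(u, v))))))


def greedy_chain(seed, seed_dir, field, params, budget=None):
    """Exhaustive greedy reference for consecutive-direction extraction.

    At every step enumerates ALL (neighbor, direction) pairs, filters by the
    forward-hemisphere / mask / FA / center-line-distance / axial-angle
    constraints, and selects by (line distance, axial angle, -probability,
    voxel index).  Independent of the package's chain module.
    """
    grid = field.grid
    d_th = params.d_th if params.d_th is not None else 0.5 * grid.diagonal
    budget = params.L_th if budget is None else budget

    dirs = field.directions_at(seed)
    best_i = min(
        range(len(dirs)), key=lambda i: axial_angle_deg(seed_dir, dirs.directions[i])
    )
    u = dirs.directions[best_i].copy()
    if float(np.dot(u, seed_dir)) < 0:
        u = -u
    path = [(tuple(seed), u, float(dirs.probabilities[best_i]))]
    visited = {tuple(seed)}
    length = 0.0
    while True:
        cur_vox, cur_dir, _ = path[-1]
        c0 = grid.voxel_center(cur_vox)
        cands = []
        for nb in bruteforce_neighbors(grid.dims, cur_vox):
            if nb in visited:
                continue
            c = grid.voxel_center(nb)
            if float(np.dot(c - c0, cur_dir)) <= 0:
                continue
            if not field.in_mask(nb):
                continue
            fa = field.fa_at(nb)
            if fa is not None and fa < params.FA_th:
                continue
            perp = min_distance_to_line(c, c0, cur_dir, n_grid=20001)
            if perp >= d_th:
                continue
            for v, d in field.directions_at(nb):
                ang = axial_angle_deg(cur_dir, v)
                if ang > params.theta_th + 1e-12:
                    continue
                cands.append((perp, ang, -d, nb, v))
        if not cands:
            break
        cands.sort(key=lambda t: (round(t[0], 9), round(t[1], 9), round(t[2], 9), t[3]))
        perp, ang, negd, nb, v = cands[0]
        step_len = float(np.linalg.norm(grid.voxel_center(nb) - c0))
        if length + step_len > budget:
            break
        if float(np.dot(v, cur_dir)) < 0:
            v = -v
        path.append((nb, v, -negd))
        visited.add(nb)
        length += step_len
    return path
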