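# Methods

`nurbstrack` estimates white-matter fiber pathways from per-voxel fiber
orientation information by fitting nonuniform rational B-spline (NURBS)
curves to chains of consecutive diffusion directions.  This note records the
model, the numerical choices, and what the synthetic phantoms do and do not
show.

## Model overview

The pipeline has three stages.

1. **Peak extraction.**  An orientation distribution function (ODF) is a
   non-negative function on the sphere whose local maxima mark fiber axes.
   Given per-voxel samples on a triangulated shell of `N` orientations, a
   vertex is retained as a peak when it is a *strict* local maximum over its
   triangulation neighborhood and *strictly* above the voxel's mean sample
   value; the mean threshold suppresses spurious noise maxima.  Retained
   values, normalized to sum to 1 within the voxel, become the diffusion
   probabilities `d_i` attached to the unit axes `v_i`.  Axes are antipodal
   (`v` ≡ `−v`); near-antipodal duplicate maxima (axial angle < 5°) are
   merged, keeping the larger value.

2. **Chain extraction.**  Diffusion directions are modeled as lines through
   voxel centers.  From a seed voxel and seed axis, the chain grows greedily
   over the 26-connected neighborhood.  A neighbor is a candidate when it is
   unvisited, lies in the strict forward hemisphere of the current
   direction, clears the anisotropy threshold `FA_th`, and its center lies
   within `d_th` of the line carried by the current direction.  Among the
   candidate (neighbor, direction) pairs whose axial angle to the current
   direction is at most `theta_th`, the winner is the pair whose neighbor
   center the direction line passes *closest* to; ties break on smaller
   axial angle, then larger `d_i`, then lexicographic voxel index.  The
   distance test is the essential difference from FACT-style propagation,
   which can hop to a diagonal neighbor whose center is far off the carried
   line.  We make the center-to-line distance the primary selection key (not
   just a gate) because pure minimal-angle selection measurably staircases
   across the width of curved bundles: a laterally adjacent voxel's axis is
   always angularly closer than the rotated axis of the next voxel along the
   curve.  Chains stop on the angle test, the length budget `L_th`
   (center-to-center), anisotropy/mask failure, or candidate exhaustion, and
   never revisit a voxel.

   Seeding is two-sided: for each axis of the seed voxel one chain runs
   forward under the full `L_th` budget and one backward under the
   remainder, and the two are spliced (backward half reversed, directions
   flipped) so the combined chain respects `L_th` and carries one polarity.

3. **Curve fitting.**  Each chain becomes one rational B-spline pathway.
   The line along a voxel's direction pierces the voxel's box at an entry
   and an exit point (slab method).  Two constructions are provided:

   * **NURBS-T** (tangent-consistent): control points are entry, center,
     exit per voxel.  The three points are collinear along the voxel's axis,
     so the control polygon is locally parallel to the diffusion direction
     at every center and the fitted curve's tangent follows the fiber
     orientation there (measured: within ~2° on smooth chains).  Only
     analytically coincident boundary points (shared facet of collinear
     face-neighbors) are merged.
   * **NURBS-G** (general): control points are the entry/exit intersection
     points only.  The exit of voxel `k` and the entry of voxel `k+1` are
     two descriptions of the same boundary crossing; when they differ (the
     step was diagonal, so the two voxel lines are laterally offset) the
     pair is collapsed to its midpoint, within half a voxel diagonal.
     Without this, the curve is forced into an S-bend at every diagonal
     step; with it, the tangent error on an arc drops by roughly half.  The
     merge is not applied in NURBS-T because it perturbs the collinear
     triples that carry the tangency property.

   Weights come from the diffusion probabilities: each control point
   inherits the `d_i` of its source voxel (a merged boundary point averages
   its two sources), and the weight vector is normalized to maximum 1 —
   only weight ratios shape a rational curve.  Curves are cubic; chains too
   short for a cubic drop to degree `n_ctrl − 1`, and chains with fewer than
   2 control points are discarded.  Knot vectors are clamped, normalized to
   [0, 1], with evenly spaced interior knots.  Pathways are sampled
   near-uniformly in arc length by chord-length reparameterization of an
   adaptively refined polyline (refinement tolerance `1e-4 ×` step).

A **multidirectional streamline** baseline integrates the direction field at
a fixed 0.02 mm step, following the nearest-axial-angle voxel axis under the
same stop rules, two-sided per seed axis.

## Parameters

| Parameter  | Meaning                                   | Default | Notes |
|------------|-------------------------------------------|---------|-------|
| `theta_th` | max axial angle between consecutive directions | 60°  | operating value used throughout |
| `L_th`     | pathway length budget (mm)                | 70      | shared by both sides of a seed |
| `FA_th`    | anisotropy stop threshold                 | 0.15    | skipped when no FA volume is attached (a mask then carries the stop role) |
| `d_th`     | center-to-line distance gate (mm)         | half the voxel space diagonal | accepts exactly the neighbors whose centers the carried line passes nearest |
| `step`     | output sampling step (mm)                 | 0.5     | metric evaluation resolution |

## Synthetic phantoms

The phantom generator produces voxel grids with analytically known fiber
geometry: straight line, circular arc (default radius 10 mm), helix,
90°-crossing line pair, and a bend — on a cubic grid of 20³ 1 mm voxels by
default, sized so the geometry fits with a margin.  A voxel joins a bundle
when its center lies within one voxel space diagonal of the curve *and* its
closest curve point is interior (the support is a tube ending flush with the
curve ends); it receives the curve's local unit tangent as an axis with
probability proportional to proximity, normalized per voxel, so a voxel
crossed by two bundles at equal distance holds two axes with d = (0.5, 0.5).
FA is 0.8 inside the support and 0.05 outside, cleanly straddling the 0.15
stop threshold.  Endpoint ROIs are two-voxel-radius balls around the curve
ends; the white-matter mask is the support plus the ROI caps.  Optional ODF
volumes are axial peaked mixtures `Σ_j d_j exp(κ((v·μ_j)² − 1))` with
relative Gaussian noise (defaults κ = 30, σ = 0.02 — sharp enough that side
lobes stay below the voxel mean, noise at a level a denoised acquisition
would show); the default sampling shell is an antipodally symmetric 64-point
golden-spiral lattice, matching the axial symmetry of ODFs.

What the phantoms do **not** emulate: Rician acquisition noise, partial
Fourier/eddy artifacts, partial-volume fading at bundle boundaries, kissing
or fanning configurations, and anatomically curved bundle cross-sections.
Passing phantom tests therefore demonstrates the geometric correctness of
peak extraction, chain selection, curve fitting and the metrics — not
robustness to scanner physics.

## Evaluation metrics

Local metrics are symmetric RMSEs over closest-point matches between the
estimated and ground-truth polylines (mean of the two directed mean squared
errors, then square root): the **spatial metric** uses point-to-segment L2
distance (mm); the **tangent metric** the axial angle between
finite-difference vertex tangents matched at the nearest vertex (radians);
the **curve metric** the absolute difference of discrete curvatures from
circumscribed circles of consecutive vertex triples (1/mm).  Matching at the
nearest *vertex* (rather than interpolating within segments) makes all three
metrics exactly zero on identical polylines.

Global connectivity classifies each pathway: **VC** when its two endpoints
fall in the two ROIs of one bundle and every sampled point stays inside the
white-matter mask; **IC** when the endpoints fall in ROIs that are not one
bundle's pair; **NC** otherwise.  The three classes partition the pathway
set, so VC + IC + NC = 100%.  **VB** counts bundles reached by at least one
valid connection, **IB** the distinct wrong ROI pairs reached by invalid
ones.  Endpoint membership uses the half-open voxel containing the endpoint.

## Numerical choices

* Strict comparisons in peak extraction: plateaus yield no peak, making
  degenerate (constant) fields deterministic.
* Basis functions use the banded Cox–de Boor triangle; parameters are
  right-continuous at interior knots with `u = 1` assigned to the last span.
* Candidate tie-breaks in chain extraction use a 1e-9 tolerance before
  falling through to the next key, ending at lexicographic voxel order, so
  tracking is bit-deterministic.
* Degenerate curves (all control points coincident) sample to a repeated
  single point with a warning rather than failing.
* The phantom's end-cap tolerance treats a projection clamped at a curve end
  (within 1e-9 of arc length 0 or L) as off-tube.

## Known limitations

* The arc phantom exposes a structural floor of the facet-intersection
  control-point construction: voxel centers sit up to half a diagonal off a
  curved truth line, so consecutive voxel lines are laterally offset and the
  fitted curve's tangent oscillates.  The tangent-metric error on the
  r = 10 mm arc plateaus near 8° (NURBS-G) / 15° (NURBS-T) and does not
  shrink with voxel size (the offsets and the transition length scale
  together).  The spatial metric is unaffected (< 0.5 mm).
* Greedy single-best selection cannot branch mid-track; branching happens
  only at multi-axis seed voxels.
* Grids are axis-aligned (diagonal NIfTI affines); oblique acquisitions must
  be resampled upstream.
* Chains step voxel-center to voxel-center, so pathway geometry is quantized
  at the voxel scale; sub-voxel seeding is not supported.
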