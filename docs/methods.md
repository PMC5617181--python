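# Methods

## Coordinate conventions

Arrays are indexed `(z, y, x)`; every public measurement API speaks physical
`(x, y, z)` micrometres.  Voxel centers carry the samples and index
`(0, 0, 0)` maps to the volume origin, so the index↔physical map is a pure
affine scaling that round-trips exactly.  Anisotropic spacing is supported
throughout even though the motivating acquisition is isotropic (0.25 μm
laterally and axially); distance transforms, arrival-time solves and mesh
extraction all take per-axis spacing.

## Reslicing model

A cross-sectional plane is attached to every centerline point; its normal is
identified with the curve tangent (center differences in the interior,
one-sided at the ends).  The in-plane axes start from a reference plane with
normal `[0,0,1]` and u along +y, carried onto the first tangent by its
azimuth/altitude rotations, and are then propagated as a rotation-minimizing
frame: the previous normal is projected onto the plane orthogonal to the
current tangent and renormalized.  This is the closed-form maximizer of
`dot(n_i, n_{i+1})` over rotations about the tangent, so per-step rotation
is minimal by construction; the discrete 1°-grid search over rotations
survives only as a test oracle.  When the projection degenerates (previous
normal parallel to the new tangent — a near-right-angle kink) the point falls
back to the azimuth/altitude construction and a warning is logged.  The
binormal is `t × n`, keeping every triad right-handed so all plane transforms
are proper rigid motions (det +1); this fixes one sign relative to the naive
`u=(0,1,0), v=(1,0,0)` reference convention.

Plane grids are `(2R+1) × (2C+1)` lattices of in-plane offsets.  The in-plane
sample spacing defaults to the smallest voxel spacing (no invented
resolution, no aliasing), and the plane half-width defaults to 6 μm, i.e.
more than twice a typical fiber radius on either side, so whole cross
sections are always captured.  Intensities are restored by trilinear
(default) or cubic-spline interpolation; trilinear reproduces affine
intensity fields exactly, which the tests exploit.  Samples falling outside
the volume are filled with 0 and flagged per sample, so fibers near stack
borders degrade visibly rather than silently.  Each plane's rigid transform
is stored; mapping segmented reslice-space points back to the original
volume inverts it, with spherical-linear interpolation of the rotation for
fractional slice indices.  The flattened CPR view is the stack of per-slice
profiles along the sweeping line (the grid row through the plane center).

## Segmentation

Histogram thresholding (256 bins) with four rules: Otsu (module default),
Kapur maximum entropy, a fixed level, and `half_max` — the threshold midway
between the background level (image median) and the bright plateau (99.5th
percentile).  The pipeline default is `half_max`: for a tube blurred by a
symmetric PSF the half-level contour is the least biased estimate of the
true boundary, whereas Otsu on these images sits well below the half level
(the histogram is dominated by background) and systematically inflates cross
sections by several percent.  Otsu/max-entropy remain available and are what
the interactive workflow this automates would offer.  Cleanup is
morphological closing plus small-component removal (26-connectivity in 3D,
8 in 2D).  A seeded, ROI-clipped region grower replaces interactive contour
drawing.  2D skeletons come from morphological thinning and are returned as
ordered pixel chains; chains are joined across gaps by greedy
nearest-endpoint pairing guarded by an explicit `max_gap` (an over-large gap
is an error naming the offending endpoints, not a silent bridge), then
interpolated by a cubic spline evaluated densely across the gaps.

## 3D centerline

Per connected component, the interior distance-to-boundary field `d` is
raised to the fourth power and used as the front speed; arrival times are
solved from the deepest voxel over the foreground (a geodesic shortest-path
solve on the `1/speed` cost field with geometric metric).  The quartic
exponent matters: with weaker centeredness weighting the minimum-time path
cuts the inner side of bends whose curvature radius approaches the tube
radius — exactly the regime of a wavy 1.3 μm fiber — and the recovered arc
length (hence waviness) biases low.  Endpoints are local arrival-time maxima
above 25 % of the global maximum, non-maximum-suppressed within 3 voxels;
each detected maximum is snapped (at most two centroid jumps) to the deepest
voxels nearby, because on a blunt tube end the arrival maximum sits on a rim
corner while the medial axis ends on-axis.  Backtracing integrates the
negative arrival-time gradient with RK4 at 0.25-voxel steps; stalls in
discrete pits hop to the lowest-arrival neighbor.  Later traces stop when
they come within half a voxel of an already-kept point and attach there, so
each component yields a tree; a trace that attaches closer to its start than
one tube diameter is a duplicate end detection and is dropped.  Components
smaller than 27 voxels are skipped with a warning; a non-elongated component
(a blob) degenerates to a single node at its deepest point.

Ordering is a depth-first traversal from a degree-1 node (or the node
farthest from the component centroid when none exists).  The main trunk is
the maximum-total-length simple path: on trees this is the weighted diameter
found by two Dijkstra sweeps (paths in trees are unique); graphs with cycles
are first reduced to a maximum-length spanning tree with a warning, since
touching fibers genuinely require user intervention.  Trunk ends are then
prolonged along their local direction while still inside the mask, capped at
1.5 μm (≈ one radius): endpoint detection stops a couple of voxels short of
a blunt end, and the straight short walk restores that length without
following strong curvature it cannot represent.  The trunk is decimated to
one point per voxel pitch, smoothed with a 1-point Gaussian to remove
backtrace jitter (a pure arc-length inflation), and refined with an
interpolating cubic B-spline evaluated at 3× the point count, uniform in
chord length, endpoints pinned.

## Morphometry

Waviness is arc length over chord, on the 3D skeleton; a 2D-restored variant
is available by composing `skeletonize_2d → fill_gaps_spline → map_back →
waviness`.  Tilt follows the textual definition — z-range over XY endpoint
distance, converted by arctan — rather than a max-z form that would depend
on the z origin; a vertical fiber reports 90° with a warning.  The surface
mesh comes from marching cubes at the 0.5 level of the (lightly presmoothed,
zero-padded) mask, followed by Taubin λ/μ smoothing; Taubin is used
precisely because plain Laplacian relaxation shrinks tube cross sections by
a few percent even with a volume constraint, and cross-sectional area is a
reported quantity.  CSA cuts the mesh with the plane normal to the local
tangent, assembles the segment soup into closed loops, and keeps the loop
whose centroid is nearest the skeleton point (a plane cuts a wavy fiber, or
neighboring fibers, more than once); area is the planar shoelace sum and the
equivalent diameter is `2·√(A/π)` — area equivalence is deterministic where
a "fitted circle" would need an arbitrary criterion.  Tangents for the
cutting planes come from center differences on a σ=2-point Gaussian-smoothed
copy of the skeleton, because inaccurate normals are the dominant outlier
source.  Points with no loop within twice the running median diameter, or
with equivalent diameter above the 6 μm threshold, are flagged and excluded
from summaries (mean ± sample SD over unflagged points).  In-plane
orientation is the second-moment principal axis of the fiber's XY
maximum-intensity projection, mapped to [0°, 180°).  Bimodal orientation
samples are split by two-means on the doubled-angle circle with circular
means/SDs reported on the 180° scale; assignment by circular distance places
values wrapping past 0° with the near-0° peak, and recovered peaks closer
than 10° (a separation below anything resolvable as two populations) are
merged into one group with a warning.

## Synthetic phantoms

The generator emulates what matters about SHG stacks of collagen: bright
tubes of radius ≈ 1.3 μm (the scale of the reported mean diameter) on dark
background, waviness near 1.37, tilt near 5°, rendered at 0.25 μm, blurred
with a 0.25 μm Gaussian PSF, with additive Gaussian detector noise (default
σ = 10 on a 200 contrast, i.e. 5 %), optional low-intensity gaps and fused
side branches.  Centerlines are straight, sinusoidal, helical or piecewise;
`amplitude_for_waviness` inverts the arc-length integral so a sinusoid hits
a prescribed tortuosity exactly over whole periods.  Ground truth (waviness,
tilt, orientation, radius profile, mask) is computed from the continuous
centerline by quadrature, so it is independent of raster resolution; the
truth orientation uses the same second-moment definition as the measurement,
which for a short wavy fiber differs by a few degrees from the end-to-end
heading — this is a property of the moment estimator, shared by measurement
and truth, not an error term.  Fixed seeds make phantoms bit-reproducible.

What the phantoms do **not** model: photon (shot) noise statistics, depth-
dependent attenuation, neighboring-fiber clutter, elastin crosstalk, and
real point-spread-function anisotropy.  Passing tests therefore demonstrate
the geometry pipeline's correctness and its noise tolerance at realistic
contrast, not segmentation robustness on arbitrary tissue.

## Pipeline and problem sizes

The driver chains reslice → segment (resliced space) → map back → 3D
skeleton → measure, and by default repeats the reslice→skeleton pass once
with the refined skeleton as the new reslicing curve.  All stages are
deterministic given the configuration; the only randomness anywhere is
phantom noise.  Tests and the acceptance script run phantoms at 128³ and
below with single fibers, which exercises every code path at the method's
native scales while keeping a full run in seconds; the same code handles
480×480×160 acquisitions, only slower.

## Known limitations

- Trunk-end extension is straight; on fibers whose curvature radius is
  comparable to the fiber radius right at the end, up to ~1 μm of end length
  is restored slightly off-curve or not at all.  Recovered waviness on noisy
  wavy phantoms varies by a few percent with the noise realization mainly
  through this end effect.
- Thresholding a PSF-blurred tube has an irreducible curvature bias of order
  (σ/r)²; at σ = 0.25 μm and r = 1.3 μm this is ~2–4 % of CSA even with the
  half-max rule.
- Touching or crossing fibers produce cycles; the spanning-tree reduction
  keeps a plausible trunk but the affected fibers should be reviewed.
- The bimodal split assumes at most two orientation populations.
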