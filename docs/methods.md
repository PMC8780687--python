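# Methods

This note documents the models, numerical choices and limitations behind
valvemorph: what the synthetic phantom does and does not emulate, how each
measurement is computed from voxel data, and where the open design choices
were resolved.

## Coordinate and orientation conventions

All geometry is in physical millimetres.  A voxel's position is its
center; the index→world map is `world = origin + direction @ (spacing *
index)` with an orthonormal direction matrix, matching the conventions of
the major medical-imaging libraries.  For the phantom, the world origin is
the volume center and the left-ventricular outflow tract (LVOT) points
along −z.  Every anatomical plane (nadir plane, commissure plane, STJ
plane) carries a unit normal oriented toward the sinotubular junction, so
"most LVOT-ward" always means *minimal signed distance* and heights are
reported as absolute values.

## The synthetic aortic-root phantom

### Geometry

The continuous phantom is built from closed-form surfaces so that every
measurement has an analytic reference:

* **Lumen.** A surface of revolution plus azimuthal sinus bulges: an LVOT
  stub (fixed 4 mm, linear taper from `lvot_radius`), a conical frustum
  from the nadir ring (`nadir_ring_radius` at `nadir_height`) to the
  commissure ring (`commissure_ring_radius` at `commissure_height`), and a
  tube of the commissure-ring radius up to `stj_height`.  Defaults
  (radii 14/13/12 mm, heights −5/+5/+10 mm, 0.5 mm isotropic voxels on a
  112³ grid) give an adult-sized root whose 19 reference values fall in
  the clinically reported ranges (eH ≈ 10 mm, comD ≈ 22.5 mm,
  NRP ≈ 88 mm).
* **Commissures and nadirs.** Commissures sit at azimuths 90°, 210°, 330°
  on the commissure ring; nadirs midway between them (30°, 150°, 270°) on
  the nadir ring.
* **Closed cusps.** Each closed cusp is *exactly* the intersection of a
  plane (through its two commissures and its nadir) with the frustum
  solid: a convex planar sector.  Its curved edge — the insertion line —
  therefore lies exactly on the wall, and its straight edge (the chord
  between the commissures) is the free margin.  Consequences used
  throughout: geodesics on the cusp are straight lines, gH = |Arantius −
  nadir| in closed form, FML is the chord length, and ciL is the arc
  length of the plane/cone intersection curve, which has a closed-form
  parameterization by azimuth and is integrated densely (4001 samples;
  discretization error ≪ 10⁻³ mm).
* **Sinus bulges.** The lumen radius gains
  `sinus_bulge · sin(πu) · cos²(1.5Δ)`, where `u` is the normalized height
  between the local insertion curve and the STJ and `Δ` the azimuthal
  distance to the nearest nadir azimuth.  The bulge vanishes with zero
  slope on the insertion curve and at the commissures, so (a) the cusp
  geometry above remains exact, (b) the nadir-plane cross-section stays
  the circle of the nadir ring (NRP = 2π·r analytic), and (c) the
  commissure-level contour is three-lobed but contains no features below
  the voxel scale — a deliberate property: a phantom must be resolvable at
  its own stated spacing or recovery tests measure resolution, not
  correctness.  The commissure-ring perimeter is the only reference value
  obtained by dense numerical integration of the analytic contour rather
  than an elementary formula.
* **Open state.** The free margin folds radially outward toward the wall
  (65% of the way); the cusp becomes a ruled surface between the insertion
  curve and the folded margin.  Its gH reference comes from a fine-mesh
  Dijkstra oracle on the analytic surface (481×121 samples, neighbor
  radius 3) instead of a closed form.

### Voxelization

A voxel is root lumen if its center satisfies the radius inequality; it is
a cusp if additionally its center lies within `cusp_thickness/2` of the
cusp sheet (exact point-to-convex-sector distance for the closed state; a
dense surface point cloud with ≈0.1 mm sampling for the open state).  Ties
between two cusp sheets go to the lower label code, making the labels
deterministic and pairwise disjoint.  `cusp_thickness ≥ 2 · spacing` is
enforced so cusps survive voxelization.

### Intensity model

Contrast-filled lumen ≈ 400 HU, a 2 mm wall shell ≈ 50 HU, padding
−3024 HU, optional calcium spheres at their specified HU (validated
> 800), and additive Gaussian noise (σ = 15 HU, seeded).  This emulates
the HU contrasts the pipeline relies on (threshold segmentation, calcium
overlays) and nothing else: no CT texture, beam hardening, motion, or
partial-volume blur.  Passing tests therefore demonstrate correctness of
the geometry/measurement chain, not robustness to clinical image quality.

## Preprocessing

`resample_to_grid` / `resample_to_box` implement the fixed crops of the
cascade through SimpleITK: isotropic output, voxel centers aligned so the
grid center coincides with the requested point, out-of-FOV voxels padded
(−3024 by convention), nearest interpolation for labels.  The
coarse-landmark box is scaled 1.5× about its center with edge-length
scaling ("1.5 times larger" is ambiguous between edge and volume scaling;
edge scaling was chosen).  The stage-2/4 crops keep a variable matrix size
covering the physical box rather than forcing 128³; the sliding window
handles larger grids with stride = patch, a final end-aligned block, and
per-voxel probability averaging in overlaps before the argmax.

Augmentation presets mirror the two training stages (landmark stage:
intensity ×[0.75, 1.25], shift [−0.25, 0.25], B-spline elastic deformation
on a 15³ control grid with shifts up to 5 voxels; segmentation stage:
rotation ±30°, intensity ×(0.7, 1.4)).  Ranges the source method leaves
unstated — landmark-stage translation, rotation and scale — are package
defaults (±10 mm, ±15°, [0.9, 1.1]).  All draws come from a caller-provided
generator, so a fixed seed is bit-reproducible.

## Landmark heatmaps

Target heatmaps are isotropic Gaussians with peak 1 at the landmark (the
peak scale is exposed as a parameter, since the balance between data and
penalty terms is configuration).  The loss is
`Σ_i Σ_x (h_i − g_i)² + α‖σ‖² + λ‖w‖²` with α = 50 and λ = 5·10⁻⁴ as
defaults; biases are not penalized.  Landmark extraction takes the maximal
voxel (ties → smallest flat index; a constant heatmap warns).  Optimizer
settings for training the detector are recorded in
`SCN_TRAINING_CONFIG` as a template only — training is out of scope.

## Mid-surface model of a cusp (sheet.py)

Segmented cusps are slabs 2–3 voxels thick.  Measurements use a
mid-surface model: PCA plane of the voxel centers, in-plane binning at the
voxel pitch, per-bin mean out-of-plane offset as a height field
(nearest-fill plus a 3×3 mean filter).  This represents any sheet that is
a graph over its PCA plane — closed leaflets and moderately folded open
ones, but not sheets folded back on themselves (a documented limitation).

* **Rim.** The 0.5-isoline of the Gaussian-smoothed (σ = 1 bin) support
  raster, followed by circular smoothing of the polyline (σ = 1.5
  vertices).  Both steps exist because contours of binary rasters
  staircase: the raw polyline overestimates arc length by up to ~15%,
  while smoothing shifts the contour position by only ~σ²·curvature/2 —
  far below a bin at leaflet scales.
* **Thickness.** Estimated from the out-of-plane residual spread
  (`t = √12 · std`, exact for a uniform slab), which is unbiased where
  volume/area ratios are not.
* **Rim deconvolution.** Voxelizing a slab dilates its in-plane support by
  half the thickness in every rim direction; the rim is offset inward by
  `t/2` before measurement.  Calibrated against the phantom's analytic
  insertion/free-margin lengths, this brings ciL and FML errors to well
  under one voxel.
* **Geodesics.** Dijkstra on the support grid with neighbor offsets up to
  Chebyshev radius 3 and straight-line 3D edge weights.  Radius-1 grid
  graphs overestimate planar distances by up to ~8%, which would exceed
  the stated geodesic tolerances; radius 3 brings the metric error under
  ~1.5%.  The endpoints themselves join the graph (edges to all nodes
  within the neighbor radius), eliminating snap-to-node quantization.

## Measurements

Planes are fit through the three nadirs (oriented toward the commissure
centroid) and the three commissures (oriented STJ-ward).  Per cusp, the
rim is split at the two vertices nearest the flanking commissures; the
wall-contacting arc is identified by mean distance to the root-region
surface (root = all labels ≥ 1, since the cusps lie inside the annotated
root); both arcs are anchored on the exact commissure coordinates.  The
Arantius body is the free-margin arc midpoint; the hinge is the attached
point with minimal signed nadir-plane distance (ties → first along the
path), which on the phantom coincides with the nadir.  eH and corH use
absolute plane distances; gH is taken literally as the surface path from
the Arantius body to the *hinge*.

Cross-section perimeters reslice the root mask onto an in-plane grid at
half the finest voxel spacing (linear interpolation; the trilinear field
carries sub-voxel boundary positions), keep the largest 2D component, and
measure the outer 0.5-contour.  Smoothing scales are fixed in physical
units — 0.3 mm on the field, 0.5 mm along the contour — making the
estimator resolution-consistent: calibrated on analytic cylinders, square
prisms and the phantom's ring perimeters, single-contour errors are a few
tenths of a millimetre at 0.4–0.6 mm spacing.  The lumen (label) contour
is measured, since the label is the segmented region; whether the
published rings used lumen or outer wall contours is not stated.

Degenerate inputs raise informative errors naming the measurement item:
collinear plane points, empty cross-sections, rims that cannot be split
into two arcs, geodesic endpoints farther than 2 voxels from the sheet.

## Post-processing

`keep_largest_component` (26-connectivity, ties → smallest flat index),
`fill_holes` (border-connected 6-connectivity background flood: closes
cavities, leaves through-tunnels intact — exact topological hole *closing*
is deliberately not implemented), and `extend_insertion_line`: rim points
of the cusp mid-surface not within 1.5 voxels of the root-region surface
are marched outward along the in-plane normal (half-voxel steps, stamping
half-thickness tubes of voxels confined to the lumen) until wall contact
or `max_gap` (default 2 mm — larger gaps, e.g. the free margin, are
reported, not bridged).  The extension iterates to an internal fixpoint,
which is what makes the operator idempotent.  The bridging path is the
package's own choice; the source procedure names the goal (reconnect the
insertion line to the wall) without an algorithm.

## Evaluation metrics

Surface voxels are foreground voxels with a 6-neighbor background voxel
(array borders count as background).  Distances are Euclidean between
surface-voxel centers in mm — no sub-voxel surface — so all metrics scale
linearly with spacing.  Both the directed Hausdorff distance (as printed
in the source formula, result→truth) and the conventional symmetric
variant are exposed; reports must state which is used.  Root evaluation
conventionally restricts both masks to the slab between the nadir plane
and the (expert-defined) STJ plane; the phantom exposes the STJ plane as a
known parameter rather than estimating it, since no algorithmic
definition exists.

## Agreement statistics

Per measurement item: Pearson's r (undefined-variance cases flagged, not
silently dropped), Bland–Altman mean difference with 1.96 SD limits,
absolute error and error rate as mean (SE = sd/√n), error-rate denominators
are the ground-truth values with zero-truth cases excluded and counted,
proportional error r_p = corr(difference, pairwise mean), and a two-sided
paired t-test with Bonferroni correction across the 19 items
(p < 0.05/19 ≈ 0.0026).  Degenerate zero-variance differences yield p = 1
(zero mean: no evidence of error) or p = 0 (constant nonzero offset).

## Problem sizes and validation scope

The test and acceptance runs use phantoms of 64³–150³ voxels at
0.4–1.0 mm spacing and five configurations spanning ring radii 8–16 mm —
sizes chosen so the full suite validates every stage in well under a
minute of compute while keeping ≥ 2 voxels of cusp thickness and
anatomically proportionate sinus bulges (≈ 15–20% of the ring radius;
larger ratios would put contour features below the voxel scale).  The
statistical calibration uses 2000 simulated replicates of 25 cases.

## Known limitations

* The phantom's cusps are planar (closed) or simply folded (open); no
  belly sag, prolapse, thickened Arantius nodules or bicuspid anatomy.
* The mid-surface model fails for sheets that are not graphs over their
  PCA plane.
* The rim deconvolution assumes the half-thickness dilation model of a
  thin slab; very thick "cusps" (thickness ≳ sheet width) would violate it.
* Intensity realism is minimal by design; no claims about trained-network
  behavior on real CT follow from these tests.
* `fill_holes` closes cavities only; topological tunnels survive.
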