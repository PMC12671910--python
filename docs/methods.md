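# Methods

This note documents the models, conventions and numerical choices behind
segcurate, in the spirit of the methods documentation of mature scientific
packages: what is computed, under which assumptions, and where design
latitude existed.

## Data model and conventions

Volumes are 3D arrays in **(Z, Y, X)** order, 0-based, with half-open
bounds for all boxes and ROIs. Label 0 is background; any nonzero integer
is one object. Label ids need not be consecutive, and an id may cover
several connected components until component splitting is applied. Voxel
sizes are physical edge lengths (z, y, x) in micrometres; fresh label ids
are always allocated as max(existing) + 1, +2, … so ids stay unique across
an edit session.

Properties follow two unit conventions, applied consistently: voxel-grid
quantities (`volume`, `volume_bbox`, `volume_filled`, `diameter`, all
intensity statistics, `bbox`) are computed on the unscaled grid, while the
remaining shape quantities (`volume_real`, axis lengths, surface-derived
scores) use coordinates scaled by the voxel size. `diameter` is kept in
voxels deliberately: it feeds tools that take voxel-unit size hints.

## Shape metrics

* **Surface area.** Two estimators are exposed. `voxel_faces` counts
  exposed voxel faces weighted by their physical face areas; it is exact
  for axis-aligned blocks but overestimates smooth surfaces (≈50% for a
  sphere in the limit). `mesh` (default) triangulates the 0.5 iso-surface
  by marching cubes after smoothing the binary indicator with a Gaussian of
  σ = 1 voxel; the raw indicator's staircase surface would plateau at a ~9%
  overestimate for spheres, whereas the smoothed iso-surface converges
  (relative error for digital balls falls from ~8% at r = 5 to ~1–2% at
  r = 20). For objects only a few voxels across, where smoothing would
  erase the object, the raw indicator is used as a fallback.
* **Compactness and smoothness** are S³/(36πV²) and S/V^(2/3) with S and V
  physical. Both are minimized by a ball; both *increase* for rougher
  objects (the conventional name "smoothness" notwithstanding — the naming
  follows the field's usage and is not "fixed" here).
* **Roughness** is the mean absolute difference between the region and its
  morphological closing (ball structuring element, default radius 2
  voxels), averaged over the voxels of the closed region — i.e. the
  covered fraction of concavities at the chosen scale. The averaging
  support is a documented choice; the quantity is dimensionless in [0, 1).
* **Axis lengths** come from the ellipsoid with equal normalized second
  central moments (scikit-image's estimator), computed on the physically
  scaled grid; `axis_ratio` = major/minor and is reported as NaN for
  degenerate (≤ 2-voxel, or planar) objects rather than raising.
* **Convexity** is convex-hull volume over region volume (≥ 1, = 1 for
  convex bodies). **Euler number** uses full 26-connectivity.
  **connected_neighbors** counts distinct other labels in 26-contact
  (face, edge or corner).

## Intensity metrics

The object **border** is the inner one-voxel shell under 26-connectivity:
object voxels adjacent to any non-object voxel (the volume boundary counts
as outside). `intensity_border_variation` is the population standard
deviation of intensity over that shell; `intensity_offset` is the
Euclidean distance (voxel units, per the voxel-grid convention above)
between the intensity-weighted centroid and the geometric centroid of the
object's voxels. Constant intensity therefore gives exactly 0 for both.

## Flagging

Rules operate on one property's distribution: strict upper/lower quartile
(boundary values are not flagged), fixed thresholds, IQR fences
(default factor 1.5) and ranges. Quantiles are linear-interpolation
(type 7) quantiles, computed per time point by default or pooled on
request. The package never chooses thresholds automatically; flagged
selections are candidates for expert review.

## Curation operators

All operators are pure (input volumes are never mutated) and return the
exact changed-label set, computed as the voxel-set diff — this is what
makes incremental property recomputation and replay logs trustworthy.
Notable semantics:

* **Fusion** assigns the smallest selected id; with label groups, fusion
  applies per group per time point. Foreground voxel count is conserved.
* **Size filtering** (delete mode) zeroes sub-threshold objects; fuse mode
  reassigns each to the neighbour with the largest contact surface
  (face-adjacency count over the 26-neighbourhood; isolated objects are
  deleted), iterating until no small object remains, smallest first.
* **Gaussian-mixture splitting** fits a mixture to in-object voxel
  coordinates. Intensity weighting is realised by resampling coordinates
  with probability proportional to (min-subtracted) intensity before the
  fit, then predicting on all voxels; a component collapsing below 2% of
  the object triggers a coordinate-only refit. Initialisation is
  k-means++ with the caller's seed recorded in the log, so splits replay
  bit-identically.
* **Axis splitting** cuts at the midpoint of the chosen axis (or the
  principal axis from second central moments); the boundary plane joins
  the upper half, so for odd extents the lower half is the smaller side.
* **Morphology** uses a digital-ball structuring element per selected
  object. Dilation, closing and convex-hull growth claim *background
  voxels only* — neighbouring objects are never overwritten. Erosion may
  delete an object (logged). Opening/closing are idempotent at fixed
  radius by construction.
* **Seed generation**: intensity minima (3×3×3 neighbourhood; a plateau
  contributes one seed at its centroid) inside objects or in background;
  distance-transform maxima with minimum-separation suppression (the
  separation parameter is in voxels, not physical units); long-axis cuts
  (the major-axis segment is divided into n+1 pieces, seeds at the n
  interior cut points); and erosion seeding (1-voxel-ball erosion until
  the object disconnects, seeds at part barycentres — objects that vanish
  before disconnecting yield a warning and no seeds).
* **Seeded watershed** floods either the intensity image or the negated
  Euclidean distance transform of the domain, restricted to a domain mask:
  the union of selected objects (which the result replaces), the
  background, or background inside a box. Regions below the volume floor
  are not created; their voxels revert to the prior content (selected
  domain) or to background. Flooding order is deterministic for fixed
  input, so results replay exactly.
* **Temporal propagation** (erode-and-fit) erodes each trusted source
  object until it lies entirely inside the union of the destination
  objects at the adjacent time, then grows the eroded cores back by
  watershed over the destination region (intensity landscape on request,
  else distance); destinations are replaced and source→result links
  returned. The fill-empty variant copies source masks minus existing
  foreground and grows them into background only.
* **Copy-paste** applies rotation + translation + isotropic scale about
  the object centroid with nearest-neighbour resampling (inverse mapping,
  so upscaling leaves no holes), writes to background only, and counts
  dropped collision voxels in the log.

## Matching and audit

Point annotations (t, z, y, x in physical units; voxel i spans
[i·s, (i+1)·s)) are assigned the label of the voxel they fall in;
background and out-of-bounds points are unassigned with reasons, and
labels receiving several points are reported (candidate missed splits),
not merged. Cross-channel matching is greedy one-to-one on descending
voxel overlap with a minimum-overlap fraction of the smaller object. An
over-segmentation audit classifies unmatched objects overlapping a
reference object by ≥ 5% of their own volume.

## Lineage

The lineage graph links (time, label) nodes across consecutive times; a
curated graph has ≤ 1 predecessor per node and binary divisions
(violations are reported, not rejected, so QC can run on raw graphs).
Overlap tracking links each object at t+1 back to the object at t with the
largest overlap (bounding-box intersection volume by default, following
the coarse-but-fast convention; voxel intersection as the precise mode).
Divisions arise when two objects at t+1 share the same best predecessor;
no global optimisation (Hungarian/ILP) is attempted.

**Tree-edit distance.** Cells (maximal single-successor chains) form
ordered trees weighted by lifetime (frame count). The distance is the
Zhang–Shasha ordered-tree edit distance with relabel cost
|ℓ_a − ℓ_b| and insert/delete cost ℓ; with these costs it is a metric
(verified against an independent exhaustive recursion and on sampled
triples in the tests). Children are ordered by (subtree total lifetime,
start label) for determinism; distances are unnormalized by default, with
an optional normalization by total lifetime. Bilateral pairing uses the
Conklin convention: `X` pairs with `X*`; unpaired cells receive NaN.
Volume-jump anomaly detection flags a ≥ 1.6× change between consecutive
nodes of one cell (no intervening division) — the signature of a missed
division or merge — plus short-lived cells and, when names are present,
cells whose Conklin sibling is absent.

## Synthetic ground truth

The generator emulates the two data regimes the operators target, not the
optics: there is no PSF, no anisotropic blur, no autofluorescence.

* **Nuclei**: non-overlapping ellipsoids (radius mean 6 voxels, radius CV
  10%, mild random elongation ≤ 1.2×) in a 48×64×64 grid, intensity =
  background 20 + per-nucleus Gaussian peak 200 + N(0, 5) noise on an
  8-bit-like scale — chosen so a fixed threshold of 100 separates
  foreground robustly. Optional touching pairs are elongated (1.4×) along
  their contact axis: fusing such a pair yields a moment-based axis ratio
  ≈ 3.4, above the 2.9 flagging threshold, while intact nuclei stay well
  below — the configuration that makes elongation flagging meaningful.
  Time-lapse frames add per-frame uniform motion (≤ 1 voxel by default)
  and binary divisions (rate per nucleus per transition, or one forced
  division for deterministic fixtures); daughters take radius r/2^(1/3) so
  volume is conserved.
* **Cells**: Voronoi tessellation of random seed points (≥ 3 voxels
  apart), with intensity = bright (200) one-voxel interfaces over dark
  (20) interiors, lightly blurred (σ 0.7) plus noise — a membrane-stain
  caricature sufficient for watershed and interface statistics.
* **Error injection** covers merge (preferring touching pairs, else
  nearest centroids), major-axis bisection (over-segmentation), deletion,
  disconnection (a carve of half-width 0.9 along the major axis at the
  25% quantile — wider than √3/2 so no 26-adjacency bridges it, leaving a
  one-id, two-component object with a small fragment), boundary jitter,
  missed divisions (daughters fused for a finite window, default 2 frames,
  so the volume-halving signature appears at separation) and broken links.
  Every action is recorded in a JSON-serializable manifest keyed by the
  seed, so tests can score detection and repair against exact truth.

What passing on this generator does **not** show: robustness to real
microscope noise structure, intensity inhomogeneity, anisotropic axial
blur, densely packed irregular shapes, or segmentation-model-specific
artifact patterns. The generator validates the *logic* of detection and
repair, not image-quality robustness.

## Pipelines

A pipeline is an ordered list of operator steps (YAML-friendly dicts) with
named intermediate selections and seed sets. After each step only the
changed labels and the labels adjacent to the changed region are
recomputed (adjacency can change `connected_neighbors` without touching a
neighbour's voxels); the tests assert this equals a full recomputation.
Runs are single-process and deterministic for a fixed config and seed,
including bit-identical label outputs on replay. On step failure the run
aborts with a partial report and the dataset retains all edits up to the
failing step.

## Problem sizes

Tests and the acceptance script use desk-scale fixtures chosen as the
package's own validation conditions: grids of 14³–48×64×64 voxels, 5–20
objects, movies of 2–6 frames, trees of ≤ 7 cells for oracle comparisons,
5 seeds for stochastic recall checks. All complete in seconds.
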