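# Methods

This note documents the models, algorithmic contracts, parameter choices
and known limitations of spinemorph.  Units are µm throughout; grids are
indexed `[z, y, x]` with spacing `(dx, dy, dz)` and voxel centers at
`(index + 0.5) × spacing`.

## Dendrite model and volumetric realization

An SWC trace is a forest of nodes (x, y, z, radius, parent).  The shaft
volume is the union of the node spheres and, for every parent–child pair,
the tapered capsule whose radius interpolates linearly along the segment
(projected arclength clamped to the segment, which yields spherical caps at
the nodes for free).  A voxel belongs to the shaft iff its **center** lies
inside this union — an unambiguous, convergent rule: the rasterized volume
approaches the analytic frustum-plus-caps volume as spacing → 0 (verified
to 5% at 0.04 µm spacing in the tests).

The **border** is the set of inside voxels with a 6-connected outside
neighbor.  Distances from the border are voxel-center Euclidean distances
honoring per-axis spacing (`scipy.ndimage.distance_transform_edt` with
`sampling`), zero on the border and inside the mask.  On every grid the map
equals an exhaustive nearest-border-voxel search; with `dz = 3 dx` an
axially adjacent voxel is `dz` away, not `dx` — anisotropy is never
flattened.

Multi-branch SWC files are accepted; dendrite length is the sum over all
parent–child segments.  Coordinates are taken as µm (the de-facto SWC
standard); the CLI offers `--unit-scale` for files in other units.

## Detection

Spine-head candidates are strict-or-plateau maxima of the 26-neighborhood.
A plateau (adjacent equal-valued maxima) contributes its lexicographically
smallest voxel, making detection deterministic under ties.  Candidates must
lie in the distance band `[dist_min, dist_max]` around the shaft border
(default 0–2 µm: spines live within ~2 µm of the shaft; the band also
excludes bright structure belonging to *other* dendrites further away) and
at or above the intensity floor.

* `intensity_min` — default **automatic**: median(image) + 0.5 × (max −
  median).  The median is a robust background estimate in sparsely labeled
  stacks, and heads are the brightest structures; a fixed absolute default
  cannot hold across bit depths.
* `min_separation` (default 0.3 µm) — greedy suppression, brightest first;
  two maxima closer than a typical head radius are one head.
* `smooth_sigma` (default 0, µm) — optional Gaussian pre-smoothing before
  maxima detection.  Local maxima are noise-sensitive; at low SNR a small
  smoothing (≈ one lateral PSF width, 0.1 µm) suppresses spurious maxima
  while the intensity floor is evaluated on the smoothed image.  Reported
  seed intensities always come from the original image.

Manual edits are coordinate-based and replayable: `add_seed` snaps to the
brightest voxel of the in-plane 5×5 window on the given slice (optionally
scanning ±k slices) and bypasses all three criteria; `remove_seed` deletes
the physically nearest seed.

## Head segmentation

The region-growing contract is: for each seed, estimate the local
background `B` as the `background_quantile` (default 5th percentile) of
intensities in a one-voxel-thick spherical shell of radius `radius_max`
(default 1.5 µm) around the seed; threshold at
`T = B + threshold_fraction × (I_seed − B)` (default fraction 0.5, the
full-width-at-half-maximum criterion); take the connected component of
`{I ≥ T}` containing the seed, clipped to `radius_max` and to voxels
outside the shaft mask.  Voxels claimable by several seeds go to the
physically nearest seed (ties to the lower label), so two seeds in one
large head produce adjacent, disjoint objects whose union is the
single-seed segmentation — exactly what the merge edit is for.  Degenerate
zero-contrast seeds (background clicks) cannot flood a flat plateau: with
`T ≤ B` growth requires strictly-above-background intensity, leaving a
few-voxel object that is flagged in the log.

The half-maximum threshold makes the recovered boundary of a blurred blob
sit at the true boundary of the underlying object to first order, which is
why head volumes are accurate despite the PSF (see Accuracy below).
Raising `threshold_fraction` can only shrink heads (monotonicity is
tested).  Heads touching the image boundary are kept but flagged truncated.

## Neck tracing

Endpoints are the head-border and shaft-border voxels minimizing the
anisotropic physical distance (exhaustively verified on small grids; ties
lexicographic).  The neck is the minimum-cost 26-connected path between
them with per-step cost

    step_length × (1 + (I_max − I(v)) / (I_max − I_min)),

I_max/I_min taken over a corridor (endpoint bounding box padded 1 µm) that
also bounds the search.  The cost is 1–2 × the step length, so bright
(neck-labeled) voxels are favored but the path can never wander
arbitrarily far through darkness — and a path through bright voxels is
never costlier than the straight voxel line.  Head and shaft interiors are
barred; per the path contract the final shaft-border voxel is dropped, so
the reported neck runs from the head border to the voxel *preceding* the
dendrite.  A corridor with no finite-cost route falls back to a
straight-line estimate with a warning.

A head with any voxel 26-adjacent to the shaft is **stubby**: neck length
0, no path (a stricter 6-adjacency option exists).  In `straight_line`
mode (a global per-run switch, for images where necks are not labeled) the
spine length estimate is the head-centroid-to-shaft-surface distance.
`retrace` re-traces from a user-imposed head-border start, with the shaft
endpoint recomputed as the border voxel nearest the new start.

## Morphometrics

Head volume = voxel count × `dx·dy·dz`.  Head surface sums exposed voxel
faces with their physical areas (`dx·dy`, `dx·dz`, `dy·dz` by
orientation): exact on blocks, and on smooth spheres it converges to
**1.5 ×** the true area (the axis-aligned-face bias of voxelized
surfaces, `E[|n_x|+|n_y|+|n_z|] = 3/2`); this factor is documented and
tested rather than hidden behind mesh extraction, which is a possible
extension.  Spine density divides the spine count by the full traced SWC
length.  All quantities are homogeneous under unit rescaling (spacing ×2 ⇒
volume ×8, surface ×4, lengths ×2 — tested).

## Synthetic phantoms

Phantoms emulate a deconvolved confocal/two-photon stack of a labeled
dendrite: a straight shaft of radius 0.35 µm along x, spines planted on
its surface — a spherical head (default radius 0.4 µm) on a cylindrical
neck (radius 0.08 µm) spanning a surface-to-surface gap (ground-truth neck
length), or a neckless stubby head sunk into the shaft.  Intensity levels
(background 10, neck 140, shaft 200, head 255) are rasterized at voxel
centers, blurred with an anisotropic Gaussian PSF (default σ_lateral
0.08 µm, σ_axial 0.25 µm), and degraded with Poisson shot noise plus
Gaussian read noise, all driven by one RNG seed (bit-reproducible).
Default spacing is (0.06, 0.06, 0.2) µm, the regime of a high-NA confocal
with 60 nm pixels and 200 nm z-steps.  SNR is defined as the noise-free
blurred peak over the background noise σ; `noise_for_snr` calibrates the
Gaussian component to hit a target SNR exactly.  Spines must be pairwise
disjoint (capsule–capsule separation test) so ground truth stays
unambiguous.

What phantoms do **not** model: curved or branching shafts, spines
overlapping in projection, labeling heterogeneity, depth-dependent
attenuation, deconvolution artifacts.  Passing phantom tests therefore
demonstrates the geometric and algorithmic correctness of the pipeline
under the stated imaging model, not performance on every real preparation
— on real data the editing operations exist precisely to correct residual
errors.

Detection scoring uses greedy nearest-first one-to-one matching of
predicted to true head centers within a match radius (0.5 µm in the
tests); with zero predictions, precision is reported as 1.0 with a
`no_predictions` flag (no false positives to count), a convention the
tests document.

## Accuracy, problem sizes and numerical choices

The test suite and `scripts/acceptance.py` run on 64×64×32-voxel phantoms
(≈ 3.8 × 3.8 × 6.4 µm) with 5–8 spines — small enough that every result is
recomputed from scratch in seconds, large enough to hold well-separated
spines at realistic spacing.  Measured on these:

* Detection: precision = recall = 1.0 noise-free with default parameters,
  and at SNR 5 with 0.1 µm pre-smoothing.
* Head volume: ~16% below the analytic sphere volume at the default PSF.
  This is the expected half-maximum bias for a blurred *curved* boundary —
  the level set shifts inward by ≈ σ²·curvature, dominated by the axial
  σ = 0.25 µm against a 0.4 µm radius — not a discretization artifact.
  Accordingly, the grid-convergence check (error decreasing as spacing is
  halved) is run in a negligible-PSF phantom where discretization is the
  only error source, and averages over the five heads' distinct sub-voxel
  placements because a single sphere's lattice-count error fluctuates
  non-monotonically between two particular grids.
* Neck length: traced lengths on straight 1.0 µm necks are short by
  ≈ 0.2 µm — the voxel-center path spans one step less than the
  surface-to-surface gap at each end — within the one-voxel-diagonal bound
  (0.217 µm at default spacing); classification of 3 stubby + 5 necked
  spines is 8/8.
* Everything is deterministic: ties in maxima, plateaus, pair selection
  and path costs all resolve lexicographically, and reruns of a fixed
  configuration are byte-identical.

## Known limitations

* Neck **width** is deliberately not estimated: it lies below confocal /
  two-photon resolution and any number produced would be PSF, not anatomy.
* Spine types beyond stubby/necked (thin vs mushroom) are not assigned;
  the continuous measurements are reported so users can apply their own
  criteria.
* Dendrite tracing itself is out of scope; the SWC model is an input
  produced by any tracing tool.
* 2D images support detection and segmentation but not neck tracing.
* The straight-line spine-length estimate and the traced neck length
  differ systematically (centroid-to-shaft vs border-to-shaft); they are
  labeled by mode in the outputs and should not be pooled.
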