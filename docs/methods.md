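# Methods

This note documents the models, algorithms, parameter choices and known
limitations of `maizefusion`, in the order the pipeline runs them.

## Coordinate conventions

All geometry is metric (meters), right-handed, z up. An orthorectified image
carries a ground sampling distance (GSD, m/pixel) and the world (x, y) of the
center of pixel (0, 0); the pixel row index grows with *decreasing* world y.
Azimuths are measured counterclockwise from +x in [0°, 360°); leaf
inclination is the angle of the midrib chord to the horizontal plane, folded
into [0°, 90°].

## Image-cloud registration

**Feature extraction.** Vegetation is separated from soil by the excess-green
index 2G − R − B thresholded with Otsu's method (clamped at zero so negative
excess green is never called vegetation), followed by a 3×3 morphological
opening and hole filling. Each connected component of at least
`min_component_px` (default 30) pixels contributes one area centroid plus
`contour_samples` (default 8) arc-length-uniform boundary samples; components
touching the border are flagged. Near-white regions (all channels > 220) are
detected separately as calibration markers.

**Cloud projection.** The cloud is parallel-projected along z and rasterized
at the image's GSD; within a pixel the top-most point wins the color. Each
point is splatted over a square whose radius adapts to the cloud's median xy
point spacing (0.55 × spacing, 1–4 px) so the raster is contiguous at any
sampling density without fattening silhouettes more than necessary. The same
binarize/extract pipeline runs on the rendering; each keypoint carries a 3D
coordinate — its own projected xy with the height of the nearest cloud point
— so matches yield (x, y) ↔ (X, Y, Z) pairs without inheriting the nearest
point's lateral jitter.

**Coarse alignment and matching.** A robust 2-point similarity consensus
aligns the two keypoint sets: sample a point pair from each side (skipping
pairs with incompatible inter-point distances), fit the closed-form
similarity, count mutual-nearest inliers within `inlier_tol`, keep the best,
refit by least squares on the inliers. Regular planting grids are nearly
invariant under one-plant shifts and 180° rotations, so (a) candidate
rotations are bounded (25° by default in the pipeline, justified by the ≤ 5°
per-date drift plus chaining slack) and (b) whenever both sides see at least
3 calibration markers, the coarse alignment uses markers only. Matching is
mutual-nearest within `max_match_dist` (default 0.12 m), one-to-one.

**DLT estimation.** With the literal sign convention

    x + (l1 X + l2 Y + l3 Z + l4) / (l9 X + l10 Y + l11 Z + 1) = 0

each correspondence contributes two rows to the stacked system B L = W
(residual V = B L − W), solved as weighted least squares via SVD-backed
`lstsq` on √P·B; the explicit normal-equation route (BᵀPB)⁻¹BᵀPW is kept as
an independent cross-check, not the solver. Six pairs are the hard minimum
(12 equations ≥ 11 unknowns); the operational gate defaults to 12 matched
points, read as "more than 11". Marker correspondences get weight 4 (they are
exact landmarks in both sensors); contour samples join only when closed
canopies leave fewer blobs than the gate, down-weighted to 0.3 and matched at
a tight 0.06 m radius, because their phase along the boundary is arbitrary.
Top-view geometry is nearly orthographic, which can leave the denominator
terms l9..l11 unidentifiable: when the design-matrix condition number exceeds
10⁷ the model is refit with l9 = l10 = l11 = 0 (8-parameter affine camera)
and flagged; a rank-deficient affine system (e.g. coplanar points) raises a
degenerate-geometry error naming the smallest singular value.

**Applying the registration.** The transform applied to the cloud is
restricted to z-rotation + uniform scale + 3D translation, extracted by
fitting a 2D similarity between the correspondences' cloud (X, Y) and their
DLT-projected (x, y). The vertical offset aligns the cloud's estimated
terrain elevation (median z inside the modal low-height bin, 2 cm bins) to
the reference date's, so the z datum is shared across the series. A second
matching/fitting pass runs on the registered cloud at a tight radius and is
accepted only if it matches at least as many pairs with no worse residual.
Models whose reprojection rms exceeds `rms_threshold` (default 0.05 m) are
refused. Dates are chained to date 1 through marker-anchored image
alignments; per-date failures are isolated and reported.

## Ground removal

**Denoising.** For each point, the mean distance to its k nearest neighbors
(default k = 8, KD-tree); points beyond the global mean + `sigma_mult`
(default 3) standard deviations are removed.

**Cloth simulation filter.** The cloud is inverted (z → −z) so terrain
becomes the upper surface. A particle grid (`grid_res`, default 0.1 m) starts
0.5 m above the inverted maximum and integrates the particle dynamics with a
damped Verlet step (dt = 0.65, damping = 0.01, gravity = 0.2 in internal
units — mirroring the reference cloth implementation); particles that
penetrate their cell's collision height are clamped and frozen. The collision
height of a cell is the inverted height of its *lowest original* point (the
first surface a falling cloth meets); empty cells borrow from the nearest
occupied cell. The internal force is `rigidness` rounds (default 2, the
flat-field setting) of spring relaxation: each movable particle moves halfway
toward its 4-neighbor average. Iteration stops when the maximum displacement
falls below `min_displacement` (default 10⁻⁴ m) or after `max_iter`
(default 500) steps. Points within `class_threshold` (default 0.05 m,
vertical) of the bilinearly interpolated, re-inverted cloth are ground. The
ground set is monotone in the threshold, and the classification always
partitions the cloud.

## Segmentation

**Seeding.** The ground-free cloud's xy histogram (`cell`, default 0.02 m)
feeds quickshift mode seeking: every cell at or above `min_density` links to
its nearest higher-density cell within `window`; link-tree roots are stem
seeds. Plateau ties are broken lexicographically by (row, col), so each
plateau yields exactly one mode and the result is deterministic. `window`
defaults to 0.25 m worth of cells — just under the 0.30 m in-row spacing —
because an unlimited search would leave only the single global maximum as a
root. `min_density` defaults to max(5, 3 × median occupied-cell count): stem
columns concentrate one to two orders of magnitude more projected points per
cell than leaf surfaces, so a multiple of the typical occupied count
separates them at any sampling density.

**Region growth.** Points within `voxel` (default 0.03 m) xy-radius of a
seed are claimed by the nearest seed; the frontier then absorbs the globally
closest unlabeled neighbor within `max_gap` (default 0.05 m), ties broken by
point index, so contested boundary points go to the nearer plant. Unreached
points stay unassigned. Guided mode replaces the fresh seeds with the
previous date's stem positions (mapped through the registration transform
when frames differ) — useful precisely when closed canopies corrupt fresh
density modes.

**Organ split.** The stem is the column of radius `r_stem` (default 0.04 m)
around the plant's density-mode xy, truncated at the top of the first
contiguous run of well-populated height bins (0.05 m bins; the floor adapts
to density as a quarter of the typical lower-column bin count, smoothed over
3 bins, so the rule is scale-free). Remaining points cluster by connectivity
within `link_gap` (0.05 m) across adjacent height bins; clusters smaller than
`min_leaf_points` (5) are absorbed into the nearest retained leaf when within
2 × `link_gap`. Leaf ids are ordered by insertion height.

**Accuracy metric.** Per-point plant accuracy uses one-to-one greedy matching
of predicted clusters to truth labels by overlap. Majority-vote mapping would
let over-segmentation pass for free, although a split plant duplicates
phenotype records; under one-to-one matching both merges and splits cost
accuracy, which is what makes the guided-vs-fresh comparison meaningful.

## Traits and assessment

Plant height is the 99th-percentile z of the plant's points minus the local
terrain elevation (median z of classified ground points within 0.2 m of the
stem axis); the percentile guards against stray high points left by
registration or segmentation. Crown size is the xy convex-hull area. Leaf
inclination and azimuth come from the midrib chord (innermost point to
outermost point, relative to the stem axis). Leaf length orders leaf points
by radial distance into 0.02 m bins, takes per-bin 3D centroids anchored by
the innermost and outermost points, and sums the polyline.

R² uses 1 − SS_res/SS_tot; MSE, RMSE and MAE use the standard error forms on
(v, v′) throughout. (One printed form of the MSE/MAE definitions substitutes
the reference mean for the estimate, which would measure reference variance
rather than error; the RMSE form and the metric names make the intent
unambiguous, so the standard forms are used for all three.) Azimuths are
compared on the circle: wrapped differences min(|Δ|, 360 − |Δ|) for the
residuals and deviations from the circular mean for the total sum of squares.
Zero-variance references flag R² as undefined rather than raising.

## Synthetic scenes: what they emulate, and what they do not

The generator reproduces the acquisition geometry the pipeline must survive:
planting grid (0.60 m × 0.30 m with ±1 cm jitter), logistic stem growth
(asymptote 2.4 m, inflection at growth stage 0.55, ±15% per-plant scale),
distichous leaves as drooping parabolic-arc midribs with lateral width —
opposite leaves of a pair share a base length and insertion angles grow more
erect with rank, both regular features of maize architecture — a dense apex
whorl (the furled emerging leaves that make the canopy top densely sampled in
real scans), rough ground (2 cm-std smooth sinusoid mixture) with drip-tape
ridges (3 cm) alongside each row, rigid white calibration boards at the field
corners, top-down occlusion (keep probability exp(−0.03 × cover rank) per
2 cm cell), and per-date rigid+scale frame offsets (rotation ≤ 5°,
translation ≤ 0.3 m, scale 0.98–1.02). Later dates in a series lose a rising
fraction (up to 40%) of points below 0.3 m, mimicking the loss of stem
returns under leaf crossing and overlap. Ground-truth traits are computed
from the generative parameters, never from the sampled points, so estimator
error is attributable to the pipeline.

Not emulated: radiometric realism (soil texture, illumination, shadows),
wind or leaf motion between sensors, multi-return LiDAR physics, lens
distortion, stitching artifacts, weeds, and lodging. Passing tests therefore
demonstrate the pipeline's geometric and algorithmic correctness under
realistic field geometry — not robustness to every radiometric or botanical
nuisance of real data. The default point density (5 × 10⁴ points/m²,
matching a survey-grade scanner at close range) is scaled down to
1.5–4 × 10³ points/m² in the test suite and benchmark so the problem sizes
stay desk-scale; all accuracy thresholds are met at those densities.

## Benchmark design

The guided-vs-fresh benchmark grows each replicate from a separable early
stage (0.3) to a closed canopy (0.6) in one step: carrying stem positions
forward pays off exactly when the later date's own density modes degrade, so
a wide growth span between dates — a season-scale gap — is the regime the
comparison is about. Two-date series, 6 plants per replicate, 10 replicates.

## Known limitations

- The DLT's denominator terms are rarely identifiable from top-view data;
  the affine fallback is the norm, and the model should be read as an
  affine camera with a projective escape hatch.
- Registration accuracy rests on the calibration markers once canopies
  merge; fields without markers degrade to blob-centroid matching, which
  carries a one-plant-shift ambiguity on regular grids.
- Leaf-level trait identities (matching leaf k across dates or to a
  reference table) assume the insertion-height ordering is stable; heavily
  occluded or merged leaves break the ordering and show up as organ-id
  mismatches in leaf-trait scores, while plant-level traits are unaffected.
- The cloth filter assumes the terrain is the lower envelope of the cloud;
  dense low foliage (< 5 cm) is classified as ground.
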