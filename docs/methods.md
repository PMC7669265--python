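# Methods

This note documents the models, conventions and parameter choices behind
`organquant`, and what the phantom-based validation does and does not show.

## Conventions

Arrays are `(Z, Y, X)`; spacing is `(dz, dy, dx)` in µm and may be
anisotropic.  Every distance, radius, σ and volume in the API is physical
(µm), converted per axis by the spacing at the point of use.  Voxel indices
are 0-based and a voxel's physical position is its centre, `index ×
spacing`.  Coordinate triples held in arrays are `(z, y, x)`; tabular
outputs name coordinates explicitly (`x_um`, `y_um`, `z_um`).

## Organ level

**Segmentation** is a deterministic pipeline — Gaussian smooth (σ default
2 µm) → global threshold (Otsu by default, or a fixed value) →
morphological closing with a physical ball (default 4 µm) → 3D hole filling
→ largest 26-connected component.  Interior filling relies on the stained
surface shell enclosing the organ, which holds for surface-outline stains;
a broken shell would leak and is reported through the mask invariant
checks (`n_components`, `n_interior_holes`).  On noise-free phantoms the
mask volume lands within ~4% of the analytic organ volume; the bias is
positive because thresholding keeps the outer half of the bright shell.

**Axis estimation** takes the dominant eigenvector of the covariance of
foreground voxel positions.  This assumes the organ is elongated: the
relative eigengap must exceed 5%, otherwise an `AmbiguousAxisError` asks
for a manual two-point axis (`axis_from_points`).  The sign convention
(largest-magnitude component positive) makes the estimate deterministic;
*polarity* — which end is distal — is anatomical knowledge the geometry
cannot supply and defaults to distal-at-+X, configurable.

**Alignment** resamples onto an isotropic grid at `min(spacing)` with
linear interpolation (order 1: no overshoot, preserves non-negativity).
The output grid is the physical bounding box of the rotated input corners,
so rotation never clips intensity; Z anisotropy is removed here, before
any reslicing.  On phantoms tilted 15–25° the estimated axis is within 2°
of truth, one alignment pass leaves a residual below 1°, and segmented
foreground volume is conserved to better than 3%.

**Slice geometry.**  Area is pixel count × pixel area.  Second moments use
the pixel-centre point cloud plus each pixel's own rectangular moment
(d²/12 terms), which makes grid-aligned rectangles exact and keeps disc
errors ~1% at 10 px radius.  `I_max ≥ I_min` are the two principal
centroidal moments.  Chord lengths are foreground extents projected onto
the principal directions — this reproduces 2a and 2b exactly for ellipses —
and each extent is floored at one pixel footprint so degenerate (collinear)
sections still report a physical width.  Circularity is the chord ratio
2R₁/2R₂; for an empty or single-pixel section it is reported as NaN rather
than 0 or 1, so profile endpoints do not fabricate shape values.
`geometry_profile` total volume Σ area·dx equals the voxel-count volume
identically, by construction.

**Mesh export** runs marching cubes at level 0.5 on a zero-padded copy of
the mask (padding closes the surface), scales to µm, and writes binary STL.
Validation voxelizes the mesh back at 3× oversampling and requires
Dice > 0.95 against the source mask.

## Cellular level

The detection chain replaces an interactively trained pixel classifier with
a deterministic filter sequence so that results are reproducible from a
config file alone:

1. background subtraction — Gaussian high-pass (default radius 15 µm) or
   morphological white top-hat;
2. 3D Gaussian blur (default σ 2 µm);
3. global threshold.  When Otsu is used it is computed over *positive*
   voxels only: exact zeros come from masking or clipping, not from tissue,
   and including them drags the threshold into the noise floor (this
   matters whenever the channel was masked by the organ segmentation);
4. 3D hole filling, then optional watershed split: Euclidean distance
   transform computed with physical sampling (avoiding Z-flattened basins),
   seeds at distance-map local maxima;
5. 26-connected labelling and physical-volume filtering
   (default 30–10⁵ µm³).

**Ordering caveat:** enhance the *unmasked* channel and apply the organ
mask afterwards.  Masking first puts the organ edge into the high-pass
filter and produces a bright rim that merges with real objects.
`run_pipeline` does this automatically.

**Watershed seed separation.**  Candidate seeds are visited in order of
decreasing distance value (ties broken lexicographically — fully
deterministic) and greedily suppressed within a physical radius, default
4 µm for the ~6 µm-radius nuclei of the phantoms.  The suppression radius
must sit *below* the seed-to-seed distance of the closest doublet to be
resolved: for nuclei touching at 1.5 radii (9 µm centre distance) the
distance-map maxima lie only ~5 µm apart, so a diameter-scale radius would
merge exactly the pairs the split exists for, while radii down to 3 µm do
not oversplit single convex nuclei (their tied plateau maxima fall well
within the radius).  This is the most sensitive split parameter and is
exposed in the config.

**Density profile.**  Slabs are half-open intervals `[x, x+50)` tiling the
mask's foreground X extent, so every centroid belongs to exactly one slab
and — the reason the protocol counts centroids rather than voxels — no
cell can be double-sampled.  Density is count divided by the mask volume
within the slab, in cells/mm³ (1 mm³ = 10⁹ µm³).  Centroids outside the
profiled extent are tallied and reported, never silently dropped.

## Molecular level

Per-slice statistics are computed over in-mask voxels by membership, not by
value, so genuinely dark in-mask voxels count.  Histogram bin edges are
shared across slices (default: 256 bins over the full integer dtype range)
so per-slice histograms sum exactly to the whole-organ histogram.

**Distal tip.**  Tip X is the extreme foreground X in the distal
direction; tip (y, z) is the foreground centroid of the most-distal slab
spanning 10% of the organ length — a deterministic stand-in for "where the
axis pierces the tip".  **Cube placement:** the cube's *distal face* sits
`offset` µm from the tip (the cube spans `[tip − offset − side, tip −
offset]` along X) and is centred on the tip (y, z) laterally.  Users
comparing against a centre-to-tip convention should add `side/2` to the
offset.  Voxel bounds are rounded to the closest achievable physical size
and recorded in the cube's provenance.  Cube statistics use raw
intensities — cross-specimen comparability presumes identical acquisition
settings; an intensity normalization step is deliberately not applied.

The paired statistic is `mean(denervated cube) / mean(innervated cube)`.

## Phantoms: what they emulate, and what they do not

The organ channel is a tapered elliptical cylinder (optionally with an
ellipsoidal distal cap) with a bright ~6 µm surface shell over a dimmer
interior; the cell channel adds isotropic Gaussian nuclei (σ = radius/2) at
rejection-sampled interior positions with a minimum separation, or
deliberately touching doublets for split testing.  Misalignment is applied
by evaluating the analytic model directly at rotated voxel coordinates
(blob centres rotated; blobs are isotropic), so the misaligned volume is
exact and the ground truth — axis, tip, per-cell positions, noise-free
fields — is analytic rather than resampled.  Sensor noise is optional
Poisson shot noise (mean = noise-free intensity) plus Gaussian read noise,
clipped at zero and quantized to the output dtype.

Standard study conditions are frozen in three helper specs:

* `detection_scenario_spec` — 50 nuclei, peak 150, read noise sd 30
  (SNR 5), anisotropic (2, 1, 1) µm grid;
* `density_scenario_spec` — uniform 5×10⁴ cells/mm³ in a straight
  cylinder, 50 µm slabs giving ~28 expected cells per slab;
* `limb_pair_scenario_spec` — a thick blastema-like organ that contains
  the 175 µm cube, ~340 nuclei (≈85 inside the cube, matching the 50–150
  expected for real blastemas), zero cell-channel background, and shot
  noise whose sd at blob peaks is peak/5.  Zero background is essential to
  the ratio statistic: any common additive pedestal biases the cube-mean
  ratio toward 1, and clipped zero-mean read noise on a zero background
  adds exactly such a pedestal, whereas Poisson noise is mean-preserving.
  The noise-free variant keeps float voxels so exactness can be asserted
  to 1e-6 without quantization.

Phantoms deliberately omit optical realism: no PSF anisotropy, light-sheet
stripes, depth attenuation, tile seams, or dense non-separable tissue.
Passing phantom validation therefore demonstrates that the *computational*
stages are correct and calibrated — not that segmentation parameters
transfer to any particular real acquisition, where thresholds and filter
radii must be tuned to the stain and optics.  In particular, dense
blastema tissue defeats single-cell segmentation at this resolution
regardless of parameters; the cube-intensity statistic exists precisely to
quantify such regions without segmenting cells.

## Numerical and degenerate-input policy

* Empty masks, empty foreground after threshold, zero in-mask voxels, and
  cubes that overhang the grid raise typed errors naming the quantity and
  the fix (required padding, threshold percentiles, overhang per axis).
* Determinism: every stochastic step is driven by an explicit seed;
  independent streams are spawned for cell placement and per-channel
  noise, so toggling noise does not move cells.  Watershed tie-breaks are
  lexicographic.  Re-running a pipeline with the same config and inputs
  reproduces CSV outputs byte-for-byte.
* Problem sizes used in the validation suite (phantom grids of ~3–10
  million voxels, 30–340 cells, 5–10 Monte-Carlo seeds) were chosen as the
  smallest at which the geometry tolerances above are comfortably met on
  discretization-error grounds; all quantities scale to larger volumes
  without algorithmic change.

## Known limitations

* PCA alignment needs an elongation eigengap; spherical early-stage
  blastemas require the manual two-point axis.
* Distal polarity cannot be inferred from geometry and must be supplied.
* The cube's lateral centring uses the tip-slab centroid; in strongly bent
  organs this differs from the local axis position.
* Marching-cubes meshes are not decimated or smoothed; they are meant for
  measurement and interchange, not rendering.
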