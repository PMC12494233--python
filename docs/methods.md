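# Methods

This document records the scientific conventions and algorithmic
definitions that histokit commits to. Anything stated here is enforced by
the test suite.

## Color models (`histokit.color`)

### Optical density and stain darkness

Transmitted light follows Beer–Lambert: `I = I0 · 10^(−OD)` per channel,
with background intensity `I0 = 255` by default. `rgb_to_od` clamps
intensities to `[1, I0]` before taking logs, so OD is finite and the
OD→RGB→OD round trip is exact to machine precision on that domain.
Stain darkness (SDA) rescales OD to an intensity-like range:
`SDA = OD · 255 / log10(I0)`.

### Deconvolution

A stain matrix `W` holds unit-norm absorption columns. Two-column
matrices are complemented with the normalized cross product of the first
two columns, so unmixing always happens in an invertible 3×3 basis and
concentration images always carry three channels (the third is the
residual "null" stain). `color_deconvolution` solves `W·c = OD` per
pixel; matrices with condition number above 1e8 are rejected with a
message naming the nearly collinear columns. Negative concentrations
(noise outside the stain cone) are clipped to zero by default;
`clip_negative=False` makes convolve∘deconvolve an exact inverse.

### Stain estimation

`estimate_stains_macenko` projects foreground OD vectors (norm ≥ 0.15)
onto the plane of the two leading singular vectors, takes the 1st and
99th percentile of the pixel angles in that plane, and maps the two
extreme directions back to 3-space. `estimate_stains_snmf` refines the
Macenko initialization by sparse nonnegative matrix factorization
(multiplicative updates, sparsity weight 0.1, 200 iterations, monotone
objective). Both return columns ordered by a deterministic convention:
the column with the larger second (green) component comes first and is
named "hematoxylin". The convention is a labeling rule, not a claim
about dye identity; comparisons in tests always use sign-blind angular
matching (`match_stain_columns`), which is invariant to column order.

### Normalization and augmentation

`reinhard_stats`/`reinhard_normalize` operate in the Ruderman
log-opponent (LMS-derived lαβ) space: per-channel mean and standard
deviation are matched to a target. Statistics of tile sets pool exactly:
`aggregate_reinhard_stats` combines per-tile means and variances with
the parallel-axis theorem, so pooled statistics equal the statistics of
the concatenated pixels to 1e-9. `deconvolution_normalize` re-expresses
concentrations in a target stain basis (complemented to 3×3, so the
residual channel is preserved); masked-out background pixels pass
through unchanged. `perturb_stain_concentration` applies a seeded affine
map `c → α·c + β` per stain channel in stain-darkness units; channels
without supplied coefficients (e.g. the null channel) are left
untouched.

## Filters (`histokit.filters`)

Scale ladders are geometric with ratio 2^(1/4). `cdog` assigns each
pixel the effective scale √(σᵢσᵢ₊₁) of the difference-of-Gaussian pair
that maximizes its response. `clog` constrains the multiscale LoG by the
distance transform of the foreground mask, so a blob's scale cannot
exceed its distance to background. `glog` uses analytic anisotropic
LoG kernels with zero DC response. `vesselness` is the Frangi ridge
filter (β = 0.5; structureness cutoff γ = half the maximum Hessian norm
per scale). Derivative kernels are truncated at 8σ because the default
truncation leaves the kernels with a small nonzero weight sum that turns
flat regions into spurious structure; a γ floor additionally keeps the
filter from adapting to numerical noise on featureless images.
Isotropic blobs are suppressed at their centers (below 0.2× a line's
response); the anisotropic ring at a blob's rim retains a partial
response (≈0.4× in our fixtures), which is inherent to Hessian-ratio
vesselness.

## Segmentation (`histokit.segmentation`)

- `detect_nuclei_kofahi`: constrained multiscale LoG maxima seed a
  watershed inside the mask.
- `max_clustering`: each pixel points to the maximum response within a
  radius; pointer chains are compressed by doubling. Ties are broken
  toward the smallest row-major linear index, which makes the output
  exactly equal to a literal per-pixel hill climb with the same rule.
- `gaussian_voting`: gradient votes accumulated along the inward normal
  over `[r_min, r_max]`, smoothed, peak-picked.
- `gvf_tracking`: Xu–Prince gradient vector flow; pixels are tracked to
  fixed points, sinks merged within a radius, labels are the basins.
- `trace_object_boundaries`: Moore neighbor tracing with Jacob's
  stopping criterion, clockwise, starting from the first boundary pixel
  in row-major order. The traced pixel set equals the object minus its
  4-connected erosion.
- `clean_label_image`: removes objects below `min_area`, objects
  touching the border, and 1-px spurs. Spur removal iteratively deletes
  pixels with fewer than three 8-neighbors whose removal does not
  locally disconnect the object; a tail pixel flush against a flat side
  has three neighbors and counts as body.
- `simple_mask`: 2-component Gaussian mixture on a KDE-smoothed sample
  of mean-RGB darkness; tissue is the darker component.
- Positive pixel counting classifies pixels in HSI space (hue as
  fraction of a turn, red = 0): within the hue/saturation gate,
  intensity bands are half-open — strong `< 100 ≤` plain `< 175 ≤` weak
  `< 245`. Counts and intensity sums are exactly additive over any tile
  partition of a slide.

## Features (`histokit.features`)

Morphometry comes from standard region properties plus boundary-based
circularity `4πA/P²` (Moore boundary length with √2 diagonal steps) and
Hu moments (rotation-invariant to 1e-6 on rasters). Fourier shape
descriptors use K = 128 arc-length-resampled boundary points; energy in
6 dyadic frequency bins is normalized by total non-DC energy, so a
circle concentrates ≥ 0.95 in the lowest bin. Intensity and gradient
statistics follow the literal formulas (entropy/energy on a 32-bin
histogram, log base 2). Haralick features are the 13 classic statistics
of min–max quantized, symmetric GLCMs averaged over 4 offsets. Global
cell-graph features use the Delaunay triangulation and its minimum
spanning tree; MST length matches Prim's algorithm to 1e-9.

## Synthetic fixtures (`histokit.synth`)

Generators are pure functions of their seeded specs. The H&E field
renders elliptical-Gaussian nuclei into the hematoxylin channel over a
constant background OD, convolves with the stain matrix, adds optional
i.i.d. Gaussian intensity noise, and clips to `[0, 255]`. Ground truth
labels are the full-width-half-maximum ellipses of the profiles
(overlaps resolved by larger profile value), and noise-free fixtures are
self-consistent: deconvolving them recovers their own concentration maps.
The default field has 12 disjoint nuclei, seed 0.

## Pipelines (`histokit.cli`)

Tiles are processed with overlap `2·ceil(2·r_max)`; objects are owned by
the tile containing their centroid; labels are renumbered canonically by
the row-major order of each object's first pixel in both the tiled and
untiled paths. Because the nuclear masks of the default fixtures decompose
into components smaller than a tile core, tiled and untiled runs are
byte-identical. `evaluate_segmentation` binarizes labels (any positive
label = foreground) and reports precision, recall, accuracy, F1, and IoU
with the convention 0 (flagged degenerate) for empty predictions against
non-empty truth, and IoU 1 when both are empty.
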