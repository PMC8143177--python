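# Methods

## Problem and model

The object of measurement is the porosity of a biopolymer film surface
as it appears in an 8-bit SEM micrograph: dark quasi-elliptical pores in
a bright, gently textured sheet. The pipeline poses pore extraction as
unsupervised pixel classification — every pixel is a point in a color
feature space, K-means partitions those points, and the darkest cluster
is declared the pore phase — followed by standard cleanup
(median despeckle, Otsu binarization, small-object removal) and
connected-component morphometry. The quantities of interest are the
region count, per-region area and perimeter, and the porosity
`% Area = 100 · total pore area / image area`, which is what ranks film
formulations against each other. A reduced chain (grey-level inversion,
Sobel 3×3 edges, Otsu, largest component) measures the silhouette of a
coated fruit in a photograph.

## Color features

RGB input (grayscale sources are replicated into three channels first)
is converted to CIE L\*a\*b\*: sRGB gamma expansion, the IEC 61966-2-1
linear-RGB→XYZ matrix, then the CIE f-function transform. The reference
white is taken as the image of unit RGB through that same matrix rather
than tabulated D65 values; the two agree to ~1e-4, but the
self-consistent choice makes every gray pixel *exactly* achromatic
(a\* = b\* = 0), which the grayscale-degeneracy logic depends on.
Clustering features default to the chromaticity pair (a\*, b\*); when
the image carries no chroma at all (max |a\*|, |b\*| < 1e-3, the case
for every SEM source), the selection falls back to L\* — without this
the chromatic feature matrix of a grayscale image would be identically
zero and the partition meaningless. Any of `L`, `La`, `Lab`, `ab` can
be requested; features are not standardized by default (the distance is
meant in L\*a\*b\* units, where Euclidean distance approximates
perceptual difference), with a z-score option for experimentation.

## Clustering and automatic K

K-means is minimized by Lloyd's algorithm: greedy k-means++ seeding
(D²-sampling with 2 + ⌊log k⌋ candidates per step, keeping the
candidate of least potential), iteration until the maximum centroid
displacement falls below `tol` (default 1e-4) or `max_iter` (default
300), an empty cluster re-seeded deterministically from the point
farthest from its centroid, and the best of `n_init` (default 10)
seeded restarts kept. After Lloyd converges, a Hartigan-style
first-variation pass applies single-point moves — using the exact
size-weighted objective change
`n_t/(n_t+1)·d(x,c_t)² − n_s/(n_s−1)·d(x,c_s)²` — until no move
improves the objective. Lloyd fixed points are not in general
stationary under single-point moves, and on small instances restarts
alone demonstrably stall in local minima that the refinement escapes;
the combination reproduces the exhaustive-partition optimum on every
tiny random instance we test. The per-iteration WCSS trace is recorded
and is non-increasing by construction.

K is selected by the elbow rule, made fully deterministic: scan
K = 2…6 (the range used for the film micrographs), record the best
restart's WCSS per K, min–max normalize both axes to [0, 1], and take
the K of maximum perpendicular distance to the chord joining the first
and last curve points. Distances under 1e-9 are snapped to zero so an
exactly linear (or flat) decline resolves by the tie rule to the
smallest K. On a strict two-tone image the curve is identically zero
from K = 2 on and the rule returns 2, matching the K = 2 used for the
hole/background split in practice; the scan may subsample pixels
(seeded, default cap 50 000) but the final fit always runs on all
pixels.

The pore cluster is identified by physics, not index: among the cluster
masks it is the one of lowest mean intensity on the original grayscale
(pores image dark), ties to the smaller mask.

## Cleanup, regions, edges

The pore mask is rendered two-tone (pores 0, background 255) and
despeckled with a 5×5 median filter — the classical remedy for
salt-and-pepper noise — then binarized at the Otsu threshold. Otsu is
computed over the 256-bin histogram as the t ∈ 0…254 maximizing
between-class variance w₀w₁(μ₀−μ₁)², ties to the smallest t; this is
definitional, and tests hold it equal to a literal 255-candidate scan
and close to the scikit-image implementation (which differs only by a
bin-center convention). By default the threshold adapts to the rendered
pore mask; `otsu_on="image"` applies it to the full grayscale instead.
Components below `min_area` (default 5 px — the smallest speck a 5×5
median can pass) are removed; connectivity defaults to 8, since pore
walls in textured films commonly touch diagonally. Sobel edges use the
standard smoothed 3×3 derivative kernels with replicated borders
(magnitude 8 on a unit ramp) and a relative threshold (default 0.2 of
the maximum magnitude); an exactly constant image yields an empty edge
mask by convention. All window operations replicate edge pixels so
output dimensions always match input.

## Morphometry

Perimeter is the length of the closed 8-connected chain of boundary
pixel centers, traced by Moore-neighbor following, with axial steps
counted 1 and diagonal steps √2 — a convention that yields fractional
perimeters for real shapes (a 2×2 block measures 4.0) and approximates
the circumference of digitized disks within a few percent for radii
≥ 10 px. Only the outer boundary is traced; interior cavities of a
region are not subtracted. A single-pixel region has perimeter 1.0 by
convention. This chain convention differs from scikit-image's
Crofton-style `regionprops` perimeter, which is therefore not used.
The fruit summary reports the largest region; its edge-point count is
the number of Sobel edge pixels inside the region's boundary band (the
one-pixel boundary dilated by one), our concrete realization of an
"edge points on the contour" count. `% Area` uses the full processed
image area as denominator. Summaries are computed in full precision
and rendered at two decimals in the CSV/JSON exports.

## Synthetic fixtures

`generate_film` renders a background at level 200 with smooth
low-frequency sinusoidal texture (amplitude 10) — smooth by design so
that Otsu's bimodality assumption holds and failures indicate pipeline
defects rather than fixture pathology — and plants dark pores at level
30. Pores are axis-aligned ellipses rasterized by the
pixel-center-inside rule, so ground-truth areas are exact integers (a
radius-5 disk is 81 px); centers are drawn by rejection sampling with a
3 px guard gap so distinct pores can never touch, even diagonally, and
more than 10 000 failed draws raise a capacity error. Noise defaults
emulate a noisy acquisition: zero-mean Gaussian σ = 8 intensity units
(clipped to range) followed by 1 % salt-and-pepper impulses.
`generate_fruit` renders a bright textured disk on a dark background
with the same rasterization rule. Identical seeds give bit-identical
images.

What the fixtures do *not* emulate: SEM charging artifacts,
depth-of-field blur, non-stationary illumination, pore-rim brightness
halos, overlapping or concave pores. Passing recovery tests therefore
demonstrates correctness of the algorithmic chain under the stated
image model, not performance on arbitrary real micrographs.

## Validation design and problem sizes

The recovery study uses 20 seeded 200×200 films with ten radius-5
circular pores (true porosity 2.025 %) — small enough that the whole
study runs in seconds, large enough that every stage is exercised. On
noise-free films the despeckle stage is disabled and recovery is
required to be exact (10 regions, 2.025 %): a 5×5 median on a clean
image only biases pore boundaries (it erodes a radius-5 disk from 81
to 69 px, the boundary pixels having fewer than 13 of 25 foreground
neighbors), so running it without noise would measure the filter, not
the pipeline. On noisy films the full default chain runs, and the
tolerance (±0.5 percentage points of porosity, region count within 5 %
in the mean) absorbs precisely that deterministic erosion bias
(≈ 0.3 pp) plus noise-induced variation. The ordering study plants
three films of decreasing porosity and requires the measured % Area to
preserve the strict order — the property that makes porosity a usable
ranking statistic across formulations.

Oracle checks pin the primitives to independent references: Otsu to a
literal scan of all 255 thresholds on random multi-level histograms,
K-means to exhaustive partition enumeration on instances of at most 10
points and 3 clusters, the knee detector to hand-evaluated
chord-distance curves, and the L\*a\*b\* conversion and clustering to
scikit-image and scikit-learn respectively.

## Known limitations

- K-means on intensity features assumes a roughly bimodal pore/film
  contrast; films with gradual pore rims or strong shading will need
  the normalization percentiles (defaults 1/99) tuned.
- The published film comparisons report percentages whose implied
  image areas differ per film (crops unrecoverable), so absolute
  porosity values are only comparable within a fixed acquisition
  geometry; the package's contract is the definition of % Area, not
  any particular printed value.
- Perimeter by boundary chain overestimates smooth contours by up to
  ~8 % at unfavorable orientations (inherent to 8-chain length
  estimators).
- Elbow selection on heavily textured images can prefer K = 3; the
  K = 2 override exists because hole/background separation is the
  analysis goal.
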