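# Methods

This note documents the models, conventions and numerical choices behind
`radonglau`, in the order the pipeline applies them.

## Preprocessing

Color images are reduced to luminance with the BT.601 weights
0.299 R + 0.587 G + 0.114 B, rounded to 8 bit. CLAHE then equalizes
contrast locally: per-tile histograms are clipped at `clip_limit`
(expressed as a fraction of the tile pixel count), the excess is
redistributed, and tile mappings are bilinearly interpolated. Defaults are
an 8×8 tile grid and clip limit 0.01; both are configuration because no
canonical values exist for fundus imagery. The implementation delegates to
`skimage.exposure.equalize_adapthist`; the degenerate constant image is
returned unchanged (its histogram has a single occupied bin), and a tile
grid finer than the image is reduced with a warning. With one tile and an
unclipped histogram, CLAHE agrees with plain global histogram equalization
to within about one gray level (both map through 256-bin CDFs); the test
suite pins this empirically.

## Radon projection

The continuous transform R(ρ, θ) = ∬ f(x, y) δ(ρ − x cosθ − y sinθ) dx dy
is discretized by treating each pixel as a point mass at its center and
splatting it onto the two nearest bins of a unit-spaced ρ grid with linear
weights. This choice makes every sinogram column sum exactly to the total
image intensity (mass conservation), which the tests assert to 1e-9
relative.

Conventions, fixed once:

- x grows with the column index, y with the row index, both measured from
  the image center (h−1)/2, (w−1)/2; θ is measured from the horizontal,
  counter-clockwise. At θ = 0 the lines are vertical and the projection is
  the column sums; at θ = 90° it is the row sums. Angles are reduced
  modulo 180°.
- The ρ grid has `ceil(hypot(h, w))` bins, symmetric about ρ = 0, so a
  300×400 image projects to exactly 500 samples and a 1×1 image to 2. The
  outermost pixel center lies at radius hypot(h−1, w−1)/2, which is always
  inside the grid (hypot(h, w) ≥ hypot(h−1, w−1) + 1 for h, w ≥ 1).
- Angle presets: `9-even` (default) reads the n·20° family (n = 1…9,
  180° ≡ 0°); `9-odd` is the complementary odd multiples of 10°; `6` and
  `18` are the uniform 30° and 10° families. The odd/even naming of the
  nine-angle families is not standardized; both plausible readings are
  shipped.

`fbp_reconstruct` provides a ramp-filtered back-projection under the same
conventions. It exists to demonstrate information preservation (with 180
angles the reconstruction correlates with the input at r ≈ 0.98 on
synthetic fundus images) and for visual inspection; it is not a production
reconstructor.

Independent checks in the test suite: exact axis-aligned sums on a 13×13
raster (whose ρ grid aligns integrally with the pixel grid), a brute-force
nearest-bin accumulation oracle (≤ 10% relative L2, the documented
discretization difference between nearest and linear splatting on smooth
images), and `skimage.transform.radon` as an external cross-check after
correcting for its rotation-center convention (it rotates about pixel
index `shape//2`, half a pixel off the true center, and its +y axis points
up; the residual offset in ρ is 0.5(cosθ − sinθ) bins).

## Unified signal length

Projection lengths vary with image resolution, so each column is resampled
to a common length with a not-a-knot cubic spline over a normalized
support. Endpoints are preserved exactly and polynomials up to degree 3
are reproduced to rounding error. Default length 690; it is a plain config
key since it trades resolution against feature count. Round-tripping a
real projection signal through 690 samples and back errs below 1e-3
relative (smooth signals); unit-variance white noise, which a spline
cannot represent, round-trips within 0.5 — both are frozen empirical
bounds, not guarantees for arbitrary inputs.

## Wavelet features

Each unified signal is decomposed exactly once into approximation (low
pass) and detail (high pass) coefficients with dyadic downsampling, using
PyWavelets with **periodization** boundary handling. Periodization is the
only standard extension under which |cA| + |cD| equals the signal length,
which the pipeline's dimension arithmetic requires: nine angles at L = 690
give exactly 9 × 690 = 6210 features. The supported families are the nine
biorthogonal wavelets bior1.1–bior3.7; default `bior1.5`. The full
coefficient blocks are concatenated per angle, deliberately avoiding
scalar summaries.

The independent oracle used in tests: for the periodized single-level
transform, c[k] = Σₘ f[m] · x[(2k + |f|/2 − m) mod N] with f the analysis
filter — a circular convolution with a fixed phase offset of half the
filter length. This closed form was verified against all nine families
before being frozen. Perfect reconstruction (biorthogonality) is asserted
to 1e-8, the Haar member in closed form, and ‖x‖² = ‖cA‖² + ‖cD‖² for the
orthogonal bior1.1.

## PCA

Features are z-scored (the cA and cD blocks live on different scales),
then reduced by an exact full-SVD PCA keeping the smallest k whose
cumulative explained-variance ratio reaches the threshold (default 0.94).
Zero-variance features are centered but not scaled; a fully constant
matrix degenerates to a single trivial component with a warning. The kept
components are orthonormal to 1e-8 and the eigenvalues match a dense
covariance eigendecomposition (`numpy.linalg.eigh` oracle). Inside
cross-validation the scaler and PCA are fitted per training fold;
`paper_mode` fits them once on all data for comparison with
whole-dataset-reduction workflows (statistically optimistic, off by
default).

## SVM and evaluation

RBF kernel K(u, v) = exp(−‖u−v‖²/(2σ²)); σ relates to the common γ
convention by γ = 1/(2σ²). The shipped preset (C = 11.313 ≈ 2^3.5,
σ = 6.727) is configuration, not something the code depends on: the proper
parameter-selection procedure is the exhaustive grid search over
2⁻¹⁰ … 2¹⁰ in 2^0.5 steps for both C and σ (41 × 41 = 1681 pairs), scored
by stratified inner cross-validation (default 5 folds) with ties broken
toward the smallest C, then the smallest σ. For the RBF kernel the search
precomputes the pairwise squared distances once and derives every
candidate kernel matrix from them.

Evaluation is stratified k-fold (default 10) with scaler, PCA and
(optionally) the grid search fitted on each training split only. Accuracy
is reported both pooled (total correct / total) and as the mean of fold
accuracies; AUC comes from the pooled held-out decision scores; undefined
ratios (zero denominators) surface as NaN with a warning rather than a
silent 0. Folds are deterministic given the seed, so a full run is
bit-stable.

## Synthetic data

The generator's defaults define the study conditions: 128×128 px images,
disc vertical semi-axis 0.22 of the smaller dimension, vertical CDR drawn
from class-conditional normals truncated to (0.05, 0.95) — normal
(mean 0.35, sd 0.05), glaucoma (0.70, 0.08) — PPA probability 0.5 for
glaucoma, six quadratic-Bézier vessels, a 15% linear illumination ramp in
a random direction, and Gaussian sensor noise with sd 4 gray levels. The
cup is rendered as a brighter concentric ellipse inside the disc (the rim
is the remaining annulus), PPA as a pale crescent weighted toward the
temporal (+x) side, and the image is tinted toward the red channel as
fundus photographs are. CDR means/sds were chosen to give overlapping but
separable classes at realistic clinical magnitudes; 128 px keeps a
200-image dataset generable and processable in seconds.

What the generator does *not* emulate: vessel-tree topology, per-sector
ISNT rim asymmetry, texture of the retinal nerve fiber layer, camera
vignetting, or inter-device color variation. Passing tests therefore show
that the pipeline recovers the radial morphology the generator encodes —
not clinical screening performance.

One consequence surfaces directly in evaluation: the shipped (C, σ)
preset, tuned for a different feature distribution, sits far from the
useful kernel bandwidth for these synthetic features (in a ~130-dimension
z-scored PCA space, typical squared distances are ~10⁴, so σ ≈ 6.7 drives
the kernel matrix toward the identity) and yields ~86% accuracy, while
running the grid search — the method's own selection procedure — reaches
~98% on the default 100+100 conditions. The end-to-end tests therefore
evaluate with per-fold grid search.

## Problem sizes in the test suite

The end-to-end checks use 100+100 images at 128×128 with the default angle
set and L = 690 (a 200 × 6210 feature matrix), 10 outer folds and 5 inner
search folds; smaller fixtures (10+10 images, reduced angle sets, L = 64)
exercise the plumbing. These sizes were chosen as the smallest at which
the class-recovery and permutation-null statistics are stable.

## Known limitations

- The Radon discretization is the O(pixels × angles) splatting transform;
  no Fourier-slice fast path is provided.
- Grid search cost grows with the full 1681-pair grid; per-fold search on
  hundreds of samples takes minutes, not seconds.
- `paper_mode` exists for comparability but reintroduces the optimism of
  whole-dataset preprocessing; keep it off for honest estimates.
- Binary labels only (normal vs glaucoma); no suspect/indeterminate class.
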