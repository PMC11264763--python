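# Methods

This note documents the models, parameter choices and numerical conventions
behind `gliomatex`, and what the synthetic test bed does and does not show.

## Preprocessing

Enhancement is global-then-local. The log normalization
`I' = round(vmax * log(1+I) / log(1+I_max))` is applied per channel with
`I_max` the channel's own maximum; an all-zero channel stays zero, and the
map is monotone, so intensity order within a channel is never disturbed.
The formula itself is a design choice: "log normalization" names a family,
and the scaled `log(1+I)` form is the member that fixes both endpoints.

CLAHE uses 8x8 contextual regions and a clip limit of 0.01 (fraction of a
region's pixels; exposed in `ExtractionConfig`). Color images are equalized
on the HSV value channel only and recombined, which leaves hue untouched —
consistent with using hue/saturation moments downstream as
illumination-robust color features. Constant channels are returned
unchanged: equalizing a single-bin histogram is the identity, and the
underlying library would otherwise map constants to full white. With a
single contextual region and no clipping the operation agrees with global
histogram equalization to within ~9 gray levels (the library normalizes the
cdf slightly differently than the textbook form).

ROI selection counts nuclei per 512x512 tile: luminance -> Otsu threshold
keeping the dark phase (hematoxylin-stained nuclei on a light background) ->
Euclidean distance transform -> local maxima with a minimum separation of
5 px (about one nucleus radius) as markers -> watershed -> count segments
with area in [15, 2000] px. All parameters are configuration values;
nothing about them is fitted. The top five tiles by count, ties broken by
(row, col) grid order, are the ROIs; selection is invariant to the order
tiles are supplied in. On the synthetic tiles the count matches the
generator's ground truth exactly for non-touching nuclei and tracks it with
Spearman rho >= 0.9 across mixed tiles.

## Texture features

**Quantization.** Gray levels are binned uniformly:
`q = floor(v * N / 2^bit_depth)` clipped to `N-1`. The standalone GLCM and
GLRLM families default to N = 64; the multi-scale LBGLCM uses 128 levels at
full resolution and 64 at deeper pyramid levels (finer quantization where
there are more pixels to populate the matrix).

**GLCM.** Distance-1 offsets at 0 degrees [0,1], 45 [-1,1], 90 [-1,0] and
135 [-1,-1]; symmetric (transpose added) and normalized to sum 1. Six
statistics per matrix; the descriptor averages the four directions
(direction-resolved output is a switch). Two deliberate conventions:

* homogeneity defaults to the variant denominator `1 + (i+j)^2` with
  0-based levels; `homogeneity="standard"` restores the classical
  `1 + (i-j)^2` inverse-difference form for interoperability;
* entropy is Shannon entropy in bits over nonzero entries; correlation on a
  constant image (sigma_x = sigma_y = 0) is defined as 0.

**GLRLM.** Maximal same-level runs along the four scan directions.
The default feature forms put the `1+(i+j)` / `1+|i-j|` denominators inside
the sums (a denominator containing the summation indices outside the sum is
ill-formed) and use central moments for the non-uniformities: `GLN` around
`mu_g`, the image's pixel-mean gray level on the 1-based index scale (so a
single-level image has GLN exactly 0), and `RLN` around `mu_r`, the mean
run length — per matrix by default, pooled over all four directions in the
multi-direction descriptor. `glrlm_formulas="standard"` switches to
Galloway's classical definitions. The counting obeys pixel conservation:
`sum_j j * count(i, j)` equals the number of scanned pixels per direction.

**LBP.** Circular neighborhoods with bilinear sampling; bit p sits at angle
`2 pi p / P` counter-clockwise from the positive x axis and the sign
function has `s(0) = 1`, so a constant image codes to all ones. Borders of
width ceil(R) are excluded. The descriptor uses the rotation-invariant
uniform (riu2) mapping — histograms of P+2 bins, exactly invariant under
90-degree rotations and axis flips — at three operating points (8,1),
(16,2), (24,3), a conventional multi-resolution ladder. The bit-order
convention only matters for the basic codes (riu2 is order-invariant).

**Heterogeneity weighting.** Over the same circular neighbors:
`V = (1/P) sum (g_i - mu)^2` and `H = 1 - (1/L) sqrt(sum (w_ij - m)^2)`
with m the neighborhood median and L = P the neighborhood size ("middle
value" and "area size" read literally). Weighted LBP histograms let each
pixel vote with V (variance mode) or 1-H (dissimilarity mode); a constant
image has zero total weight and yields the documented all-zero vector
rather than NaN. Neighborhoods constant to within bilinear rounding are
snapped to exactly V = 0, H = 1 so the degenerate contracts hold
bit-for-bit.

**Multi-scale LBGLCM.** The basic-LBP-coded image (2^P codes re-quantized
to the configured level count) is fed to the GLCM machinery; the pyramid is
Gaussian smoothing (sigma = 1) followed by stride-2 decimation with floor
size semantics, 3 levels by default (a 128 px tile supports exactly 3).
Per-level blocks are concatenated level 0 upward. Normalization of the
blocks is deferred to the fused-feature scaler (below) so that no test-set
statistics can leak into the descriptor; per-column min-max with training
statistics subsumes per-block scaling.

## Color features

Color moments use root-moment forms, not standardized moments: sigma is the
RMS deviation with a 1/N denominator, skewness the signed cube root of the
third central moment mean (sign preserved via the odd real root), kurtosis
the fourth root of the non-negative fourth moment mean (total real root).
`moments="standardized"` switches to the conventional dimensionless
statistics. HSV moments cover hue (degrees, [0, 360)) and saturation only;
the value channel is excluded as the illumination-carrying component
(switchable).

RSHD quantizes RGB into 64 shades (4 uniform bins per channel,
`index = qR*16 + qG*4 + qB`) and classifies every 2x2 window, per shade, by
its count of matching pixels (0-4). The five count classes are the
rotation-orbit classes of 2x2 binary patterns once the two-pixel class
merges adjacent and diagonal pairs; this is an interpretation of the five
"rotation-invariant structure elements" the descriptor family calls for,
not a reproduction of any specific published element set. The 64x5 grid is
L1-normalized; invariance to right-angle rotations and flips is exact
(2x2 windows map bijectively), and cosine similarity under factor-2
downsampling stays above 0.9 on the synthetic tiles.

## Reduction

Feature blocks are concatenated in a fixed family order and every column is
min-max scaled to [0, 1] with statistics frozen on the training split — NMF
requires non-negative input, and test rows must see exactly the training
transform. The NMF is the standard multiplicative-update minimization of
the Frobenius error with a 1e-12 additive guard in the denominators;
initialization is seeded uniform noise scaled by `sqrt(mean(X)/k)`, so fits
are bitwise reproducible. Defaults: k = 32, tol = 1e-4 relative error
change, max_iter = 500. The per-iteration error trace is recorded and is
non-increasing (asserted in tests with a 1e-9 relative numerical guard;
multiplicative updates are monotone in exact arithmetic but float rounding
can tick the error by ~1e-16 near convergence). New rows are projected by
non-negative least squares against the frozen H. A rank-1 matrix at k = 1
is recovered to fit error <= 1e-6.

## Classification

* **RBF-SVM**: `k(x, x') = exp(-gamma ||x - x'||^2)`; gamma in
  {1e-5, 1e-4, 1e-3} and C in {0.1, 1, 10, 100, 1000, 10000} chosen by
  inner 3-fold CV accuracy, ties resolved toward the smaller C then the
  smaller gamma (scanning the grid in ascending order and accepting only
  strict improvements makes this deterministic). Multiclass is one-vs-one.
* **Fast large margin**: linear one-vs-rest minimization of
  `0.5 ||w||^2 + C sum max(0, 1 - y(w.x + b))` by guarded subgradient
  descent — a step is halved until it strictly lowers the objective, so the
  per-epoch trace is non-increasing by construction — with early stopping
  on relative objective change. Default C = 10: on [0, 1]-scaled NMF
  components the squared-norm term otherwise dominates the data term and
  the model underfits. Per-sample margins `rho = y f(x)` are exposed for
  diagnostics.
* **Random tree**: a single binary tree choosing, at each node, the split
  with the largest information gain `IG = E(parent) - weighted E(children)`
  (Shannon entropy in bits) over a random feature subset (sqrt of the
  feature count), seeded. Single-class training data yields a depth-0
  constant predictor rather than an error.

The ensemble trains all three on identical rows and takes the row-wise
majority vote; a three-way tie falls back to the first base model (the
SVM) — a fixed, documented rule, since "mode" is undefined for ties. For
ROC curves a continuous per-class score averages the vote fraction with a
softmax of the SVM's one-vs-rest decision values.

## Evaluation protocol

One-vs-rest confusion counts feed the five metrics ACC, TPR, PPV, SPC and
DSC = 2TP/(2TP+FP+FN); DSC equals the harmonic mean of PPV and TPR whenever
both are defined, and zero-denominator metrics are defined as 0 with a
logged warning. Cross-validation is stratified by label and grouped by
parent image, so ROIs from one parent never straddle a train/test boundary;
the scaler, the NMF basis and all three classifiers are refit inside every
training fold. The 40% holdout is stratified and group-integral. AUC is the
trapezoidal one-vs-rest area with midrank tie handling.

## The synthetic test bed

`generate_texture_dataset` emulates H&E tiles procedurally: a tinted
background plus Gaussian pixel noise (sigma 5) and dark, anti-aliased
nucleus disks (radius 3-7 px) placed by rejection sampling so they rarely
touch. The default four classes form a ladder in both nucleus density
(10/25/45/70 per 128 px tile) and background tint, so texture families and
color families each carry class signal — mirroring the claim that their
fusion is what makes the grader work. Every image records its true nucleus
count, giving the watershed counter a ground truth. Augmentation
(right-angle rotations, flips, edge-replicated shifts, bilinear zoom in
[0.5, 2]) is exact where exactness is possible; magnitudes are
configuration, not fixed constants.

What passing on this bed shows: every formula agrees with independent
brute-force oracles; the exact invariances hold; the full pipeline recovers
a 4-class structure whose texture/color separations are of the kind, but
not the difficulty, found in real slides. What it does not show: robustness
to stain variability, scanner differences, touching and overlapping nuclei
at real densities, or the intra-class heterogeneity of actual gliomas — on
real whole-slide data all tunable defaults (watershed bounds, quantization
levels, clip limit, k) would need study-level validation.

## Problem sizes and determinism

The study set used by the tests and the acceptance script is 4 classes x
25 images at 128 px (100 ROIs, 559 raw features), chosen so the full
10-fold protocol — feature extraction included — completes in well under a
minute on one CPU while still exercising every stage. All randomness
(generator, fold shuffling, NMF init, tree subsampling) flows from a single
integer seed; two identical seeded runs produce byte-identical feature
tables, fold assignments and reports.

## Known limitations

* The GLRLM variant formulas are not Galloway's; cross-study comparisons
  should use the `standard` switch.
* The watershed counter is tuned for dark, roughly convex nuclei of 3-7 px
  radius at the fixture scale; real 40x tiles need different area bounds.
* The fast-large-margin solver is a simple guarded subgradient method —
  robust and monotone, but slower to high precision than dedicated QP or
  dual coordinate solvers.
* `sweep_k` refits the whole head per (k, fold) and is the one genuinely
  expensive operation; sweeping 2..100 as a grid is feasible but takes
  minutes, so the default examples use small grids.
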