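# Methods

`charmkit` implements segmentation-free whole-image classification for
microscopy: a CHARM-style ("Compound Hierarchy of Algorithms Representing
Morphology") feature vector computed on the whole image and on transform
domains of the image, dimension reduction by PCA, classification by LDA
(with a Fisher-weighted WND classifier as the historical baseline), and
batch-aware repeated cross-validation. This note records the model, the
conventions chosen where the method family leaves room, and what the
synthetic fixtures do and do not demonstrate.

## Image model and normalization

Input images are single-channel rasters (8- or 16-bit TIFF/PNG/JPEG;
multi-channel samples are handled one channel at a time, and per-channel
vectors are concatenated). Intensities are divided by the bit-depth
full-scale value (255 or 65535) — not min–max scaled per image — so that
global brightness differences between images remain visible to the
features. This is deliberate: batch artifacts such as illumination drift
are image-wide signals, and the validation layer, not the loader, is
responsible for keeping them out of the accuracy estimate. No
illumination correction or denoising is applied. Images smaller than
8×8 are rejected; the Chebyshev decomposition additionally requires at
least 400 pixels.

## Image levels

Starred feature groups are extracted on six "levels":

| code | domain |
|------|--------|
| IM | the original image (identity, no rescaling) |
| W  | one-level orthonormal 2-D Haar wavelet transform, four subbands tiled |
| C  | discrete Chebyshev transform (20×20 coefficients) |
| F  | modulus of the 2-D DFT (unnormalized, DC at the corner) |
| WF | Haar transform of the Fourier modulus |
| CF | Chebyshev transform of the Fourier modulus |

Conventions the method family does not pin down, fixed here:

* **Wavelet depth**: a single decomposition level, subbands tiled
  `[[A, H], [V, D]]` into a matrix of the (even-truncated) input size.
  One level keeps every starred feature group computable on the result;
  orthonormal scaling makes the tiling exactly energy-conserving.
* **Chebyshev transform**: coefficients of the least-squares projection
  of the image onto the tensor basis T_i(x)·T_j(y), i,j < 20, with pixel
  centers mapped affinely onto [−1, 1]². The tensor structure lets the
  full least-squares problem factor into two small pseudo-inverse
  solves. Order 20 (400 coefficients) is the conventional choice and is
  configurable.
* **Rescaling**: each transform level is min–max rescaled to [0, 1]
  before feature extraction so histogram-type features have a defined
  range on transform domains; ranges at floating round-off scale
  (relative 1e-12) count as constant and map to zero, so the flat
  spectrum of a spike matrix does not blow up into amplified noise. The
  IM level is not rescaled (it is already in [0, 1], and rescaling would
  discard real global-brightness information).
* **Fourier**: modulus only; phase is discarded. No windowing.

## The 953-element feature vector

Per channel, six starred groups are computed on all six levels and four
base groups on IM only:

| group | size | levels |
|-------|------|--------|
| pixel statistics (starred subset) | 6 | all |
| moments | 4 | all |
| multiscale histograms (3+5+7+9 bins) | 24 | all |
| Gabor features | 2 | all |
| Haralick textures (13 stats × 4 directions × 2 distances) | 104 | all |
| Tamura textures | 6 | all |
| pixel statistics (plain subset) | 9 | IM |
| edge statistics | 4 | IM |
| Chebyshev statistics (32-bin coefficient histogram) | 32 | IM |
| Chebyshev–Fourier statistics | 32 | IM |

Total: 146 × 6 + 77 = **953**. The column order is fixed
(`group.item@level`), and `feature_names()` is the stable contract.
Group ablation (`exclude_groups=`) removes a starred group from every
level at once.

Numerical conventions:

* **Zero-variance inputs**: skewness, kurtosis and Tamura contrast are
  defined as 0. Population variances throughout. A variance at floating
  cancellation scale (≤ (1e-12 × scale)²) counts as zero — `np.var` of a
  bitwise-constant array is ~1e-33, not 0, and would otherwise feed NaN
  through scipy's moment routines.
* **Thresholds**: every unspecified threshold is Otsu's. On a constant
  input the threshold equals the constant and nothing lies above it
  (the three thresholded statistics are then 0).
* **Haralick**: intensities quantized to 8 equal-width bins on [0, 1];
  symmetric, normalized co-occurrence matrices for directions
  0°/45°/90°/135° at distances 1 and 2 (offset of d pixels along each
  direction — built in-package because `skimage.graycomatrix` rounds
  `d·(sin θ, cos θ)` and collapses the distance-2 diagonals onto
  distance 1). The 13 statistics are the standard set; sum-variance is
  centered on sum-average; correlation and IMC1 fall back to 0 for
  degenerate marginals; natural logarithms.
* **Gabor**: one center frequency (0.25 cycles/pixel, 1-octave
  bandwidth) at four orientations; the two features are the mean and
  variance over orientations of the mean response magnitude (texture
  energy and orientation anisotropy). The orientation set is closed
  under 90° rotation, which the tests exploit.
* **Tamura**: contrast is σ/α₄^¼; coarseness uses the classic 2^k
  averaging scheme (k ≤ 5) with circular shifts at the borders, ties
  preferring the smallest window; directionality is the sum of squared
  bin masses of the 16-bin gradient-orientation histogram over pixels
  whose gradient magnitude exceeds its Otsu threshold; plus a 3-bin
  histogram of the per-pixel best-window map.
* **Mode**: center of the most populated of 256 bins on [0, 1].

## Dimension reduction and classifiers

**PCA–LDA** (the main path). Features are z-scored (zero-variance
columns get divisor 1), and the minimal leading set of principal
components reaching the variance threshold — default **0.98** — is
retained. Standardization before PCA is a deliberate choice: raw
CHARM-style features span wildly different scales (counts, entropies,
histogram masses), so covariance-PCA would be dominated by a few
large-scale columns. LDA uses the pooled within-class covariance
(divisor n − C) with a ridge of 1e-8·trace/d on the diagonal so the
discriminant is defined even when components approach the sample count;
priors default to empirical frequencies; prediction ties break toward
the lexicographically first class.

**Fisher + WND** (the baseline path). Per-feature Fisher discriminant
scores w_f = Var_c(μ_fc) / mean_c(σ²_fc) (unweighted class means,
population variances; a perfect separator — zero within, positive
between — gets a 1e12 sentinel, a constant feature 0). The top
round(0.15·n) features by weight are retained (ties by ascending index;
round half away from zero, so 15 % of 953 is 143). Features are
standardized before weighting. The WND classifier scores class c as the
mean over its training samples of D(x,t)^p with
D = Σ w_f²(x_f − t_f)² and p = −5; an exact match (D = 0) short-circuits
to that sample's class. The Tanimoto similarity of selected index sets
across resampled fits is exposed as a selection-stability diagnostic.

## Validation

Cross-validation is **unstratified k-fold** (default k = 10): folds are
drawn without regard to class labels. With `grouping="by_batch"`, whole
acquisition batches are assigned to folds (largest batch first into the
currently smallest fold, batch order randomized within equal sizes), so
no batch ever appears on both sides of a split — the safeguard against
image-wide batch artifacts masquerading as class signal. Every
statistic, including standardization, PCA, Fisher weights and the
classifier fit, is computed on the training folds only. Accuracy is the
pooled (micro-averaged) fraction correct over all held-out folds, which
is robust to the unequal fold sizes batch grouping produces. A training
partition missing a class scores that class's test samples as errors
(with a warning) rather than aborting — unstratified CV keeps its
denominator.

Experiments are repeated (default **100 runs**, run r seeded seed + r)
and summarized by the **median and standard deviation** of the run
accuracies. The **lone 4-fold** baseline — a single stratified 75/25
split — is provided for comparison; on a partially separable fixture
its run-to-run standard deviation exceeds 10-fold's, the stability
argument for k-fold.

The **permutation null** shuffles class labels with a fresh seed before
each run and reports the null median/std plus a one-sided empirical
p-value with the add-one convention, p = (1 + #{null ≥ observed}) /
(n_runs + 1). On a 32-sample balanced two-class set the null median
lands on the 1/32 accuracy grid around 0.47–0.50; the slight
below-chance center is the expected anti-correlation bias of
unstratified CV under permutation (a class over-represented in the
training folds is under-represented in the test fold, and empirical
priors push predictions toward the training majority).

## Synthetic fixtures

The generator produces labeled image sets from four texture families
(stripes, checkerboard, Gaussian blobs, band-limited filtered noise)
with per-class structure scale and contrast, additive Gaussian pixel
noise, and a batch plan: per-batch global brightness offsets (additive
by default, multiplicative gain optional — additive matches the
lamp-drift picture) drawn uniformly within ±amplitude, either mixed
across classes or *confounded* (each batch belongs to one class). All
randomness flows from the spec seed; datasets regenerate bit-exactly.

Canonical fixtures:

* **separable**: 2 × 16 images, stripes (4 px) vs checkerboard (6 px),
  contrast 0.5, noise σ = 0.05, 64×64. Deterministic periodic textures
  make the class signal identical across generator seeds; the PCA-LDA
  pipeline reaches median 10-fold accuracy 1.0. Its size matches a
  small two-class screening set and it doubles as the stand-in for the
  permutation-null calibration.
* **confounded** (the leakage fixture): 2 × 15 images in 10 batches of
  3, zero texture contrast, zero pixel noise, per-batch brightness
  offsets within ±0.2. Images within a batch are exact replicates — the
  limiting case of sub-images cropped from one field or repeated
  acquisitions of one well, which is how batch leakage arises in real
  benchmark collections. The class signal is the batch artifact and
  nothing else. Naive folds let the WND classifier memorize each
  batch's brightness (median accuracy 1.0); batch-grouped folds reduce
  it to within the permutation null. Ten batches keep the default
  k = 10 feasible under grouping.
* **null**: two classes with identical generative specs; any validated
  accuracy should sit at chance.

What these fixtures do **not** show: real microscopy batch effects are
high-dimensional (focus, staining, density — not a single brightness
scalar), and real within-batch images differ in content. With nonzero
iid pixel noise on featureless images, z-scoring inflates hundreds of
noise-only features to unit variance and a purely scalar artifact is
*not* memorizable by either pipeline — the demonstration deliberately
uses the replicate limit, where leakage is unambiguous. Conversely, the
PCA-LDA path memorizes the scalar artifact only partially
(seed-dependent, ≈0.8–1.0 naive accuracy) because the 98 % variance
cut drops some of the fine nonlinear structure of a one-parameter
artifact curve; the WND path, whose inverse-fifth-power distance sum is
dominated by nearest neighbors, memorizes it perfectly and is the
classifier used in the leakage demonstration. Passing these tests shows
the validation machinery does what it claims on constructed artifacts;
it does not certify accuracy figures on real screens.

## Problem sizes and runtime

Feature extraction runs at roughly 0.1 s per 64×64 image (it dominates
pipeline cost, which is why extracted features are persisted to CSV
between the CLI's `extract` and `validate` steps). The test-suite
fixtures use 28–32 images; repeated validation and permutation nulls
use the protocol's 100 runs. The full suite finishes in well under a
minute on one CPU.

## Known limitations

* The feature set follows the CHARM construction in groups and levels
  but is a documented re-completion, not a bit-compatible reimplementation
  of any existing tool's vector; absolute feature values are not
  comparable across implementations.
* LDA's ridge is a fixed small multiple of the covariance trace; very
  ill-conditioned problems may prefer proper shrinkage estimation,
  which is out of scope.
* Multi-page TIFF, PNG and JPEG are supported; proprietary microscopy
  containers are not.
* `lone_four_fold_split` requires ≥ 4 samples per class; batch-grouped
  folding requires at least k distinct batches.
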