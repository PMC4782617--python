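# Methods

## Problem and model

`texdirect` addresses binary screening of 2-D grayscale images: label +1
("abnormal") for images containing localized high-frequency, high-contrast
texture anomalies, −1 ("normal") otherwise. The modeling assumption is
that abnormality manifests as *abrupt and frequent variation in image
texture* rather than in any specific shape or location, so features are
computed from whole-image coefficient distributions and no segmentation or
region-of-interest step exists anywhere in the pipeline.

The pipeline factors into four stages, each independently testable:

1. wavelet analysis → HH detail subband (the high-frequency carrier);
2. Gabor filter bank → directional resolution of that carrier;
3. entropy/uniformity of coefficient histograms → a low-dimensional,
   spatially invariant descriptor;
4. polynomial-kernel SVM under cross-validation → the decision rule and
   its performance estimate.

## Wavelet stage

The 2-D DWT is implemented directly as separable filtering: each row is
extended at the boundary, convolved with the low-pass g(n) and high-pass
h(n) analysis filters, and decimated by 2; the same is then applied to the
columns of each result, yielding LL, LH, HL, HH. Decimation keeps samples
at phase L/2 (L = filter length), and the output length is ceil(n/2)
regardless of boundary rule. Writing the transform out (rather than
calling a library decomposition) keeps the boundary/dimension contract
explicit; PyWavelets supplies the Daubechies filter taps and serves as an
independent oracle — in periodization mode the decomposition reproduces
`pywt.dwt2(..., mode="periodization")` to 1e-10, which the test suite
asserts alongside a brute-force filter-and-decimate oracle.

Choices:

* **Wavelet**: Daubechies-4 in the 4-vanishing-moment sense (8 taps,
  PyWavelets "db4"). The 4-tap reading ("db2") exists in other naming
  traditions; the spec of the filters is pluggable via `WaveletSpec` if a
  user needs it.
* **Boundary**: symmetric (half-sample mirror) extension by default —
  natural for non-periodic image content; periodization is available and
  is the mode under which the PyWavelets cross-check is exact.
* **Levels**: 1 and 2. Level 2 recurses on LL (standard Mallat pyramid);
  deeper levels are gated behind `allow_deep=True` because nothing here
  validates them.
* **Intensity scale**: images are float64 in [0, 1]; integer inputs are
  divided by their dtype maximum, color inputs reduced to BT.601
  luminance.

## Gabor stage

Kernels sample the real Gabor formula exactly at integer offsets, so the
center weight is exactly 1 and kernels for θ and θ+π coincide. Support is
an odd square of half-width `max(3, ceil(3·max(σx, σy)))`; 3σ truncation
retains >99% of the Gaussian envelope mass. Filtering is true spatial
convolution (kernel flipped) with symmetric padding, delegated to
`scipy.ndimage.convolve` and verified against a brute-force double sum.

* **Bank**: 4 orientations × 3 frequencies = 12 filters, enumerated
  frequency-major, orientation-minor; this order defines feature
  subscripts and is recorded in feature names and run logs.
* **Frequencies** are cycles per pixel taken literally, so f ∈ {2, 2.5, 3}
  aliases on the integer lattice. This is intentional: the descriptor is
  the statistics of the filtered coefficients, not a band-pass analysis.
  `frequency_scale` (default 1.0) rescales the bank for users who want
  sub-Nyquist responses.
* **Sigmas**: σx = σy = 1 by default; `FilterBankConfig.mammogram(tau)`
  builds the anisotropic scheme σx = τ/2.35 (τ = Gaussian FWHM in pixels,
  default 2.35 ⇒ σx = 1), σy = 8σx used for mammographic texture.
* Only the real part is computed; the quadrature component is an
  extension point.

## Features

For each coefficient image, p(z) is the relative frequency over `n_bins`
equal-width bins spanning that image's [min, max]; then E = −Σ p log₂ p
and U = Σ p². Conventions: 256 bins (8-bit gray-level convention), log
base 2 (any fixed base is an affine rescaling the SVM absorbs),
0·log 0 := 0, and per-image binning — which makes E and U invariant to
pixel permutation and to positive rescaling of the image. Coefficient
spread below 1e-12 (relative) counts as constant, so numerically
annihilated subbands (HH of a flat image) give the degenerate histogram
E = 0, U = 1 rather than an arbitrary histogram of float residue.

One behavior worth knowing when interpreting features: a few large anomaly
coefficients stretch the per-image bin range, concentrating the bulk of
near-zero background coefficients into few bins — so on the synthetic
data *abnormal* images have **lower** HH-Gabor entropy and higher
uniformity than normal ones. The direction is pinned as a regression test;
the SVM is direction-agnostic.

## Classifier and evaluation

The soft-margin dual QP is solved by libsvm (scikit-learn `SVC`) with
`gamma=1, coef0=1`, making the kernel exactly (⟨xᵢ, x⟩ + 1)^d; d = 2 and
C = 1 by default (C is nowhere pinned by the problem; it is recorded in
every report). Solver tolerance is 1e-6 — near-degenerate support sets
depend on it. The fitted machine is stored as support vectors, dual
coefficients yᵢαᵢ* and bias b*, and **predictions are evaluated from that
expansion in-package**, with the tie rule sign(0) → +1 (abnormal): in a
screening context an undecidable case escalates rather than clears. No
feature standardization is applied by default (E is bounded by log₂ 256,
U by 1).

Cross-validation: stratified seeded tenfold (requires ≥ 10 samples per
class) or leave-one-out (≥ 3 samples). Reports carry per-fold CCR,
sensitivity and specificity with mean ± sd (population sd) over folds, and
pooled metrics over all held-out predictions. A fold without positives
(or negatives) has undefined sensitivity (specificity); such NaNs are
excluded from the mean ± sd with a warning — stratification makes them
rare. The identity CCR = (Se·n₊ + Sp·n₋)/n holds exactly for the pooled
metrics and is asserted on every report in the tests.

## Synthetic data: what it emulates and what it does not

Normal images are unit-range-normalized Gaussian-blurred white noise —
smooth, low-frequency "tissue". Abnormal images add hard-edged bright
discs (the small-bright-spot archetype of clustered calcifications or
exudates) and optionally one oriented bright streak (exercising the
bank's directional selectivity). Generation is a pure function of
(config, seed, index); background and anomaly geometry use independent
streams, so a zero-amplitude anomaly reproduces the normal image exactly.

Defaults — 128×128, 40 images per class, blur σ = 4 px, 6 discs of radius
2 at amplitude 0.25, one π/4 streak, seed 7 — put clear anomaly energy in
the HH subband (the generator's contract: mean |HH1| of abnormal images
exceeds that of normal images, asserted in tests). Under these conditions
every feature mode classifies perfectly; the regime is separable by
construction.

`subtle_anomaly_config()` (blur σ = 16 px, disc amplitude 0.001, no
streak, 20 per class) is the documented hard regime: anomalies sit far
below background contrast, raw-image Gabor features lose them, and the
Gabor-only mode collapses toward predicting one class (at the pinned
seeds: sensitivity 0.25 vs specificity 0.85, CCR 0.55) while the hybrid
HH-based features stay at 100% on the same folds.

What passing on this generator does **not** show: robustness to
acquisition artifacts, intensity inhomogeneity, anatomical variability,
or anomaly morphologies beyond generic discs/streaks; there is no
modality-specific realism (one generator serves for all "modalities"
since the method itself is modality-agnostic). Results on synthetic data
bound nothing about clinical images.

## Problem sizes

The test suite and the acceptance script run the full experiment at the
default 80-image, 128×128 scale (seconds on one core) and use 64×64 /
8–24-image configurations for pipeline-level unit tests; oracle
comparisons use 8×8–16×16 images where brute-force references are exact
and cheap.

## Known limitations

* Binary labels only; multi-pathology classification is out of scope.
* Only the polynomial kernel is wired; no probability calibration or ROC
  analysis.
* The literal cycles-per-pixel frequencies mean the bank's orientation
  selectivity on real imagery differs from a tuned sub-Nyquist bank;
  `frequency_scale` exists but is untested beyond unit level.
* Histogram binning of continuous coefficients is a modeling choice; a
  gray-level quantization scheme would give different absolute E/U values
  (the cross-validated comparison between modes is unaffected in our
  tests, but absolute feature values are convention-dependent).
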