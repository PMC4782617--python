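# texdirect

Screening of 2-D grayscale images — normal tissue versus abnormal tissue
with high-contrast, high-frequency anomalies (clustered bright spots,
oriented streaks) — from **directional high-frequency texture features**.

Many pathologies visible in mammograms, retinal photographs and brain MR
slices share one signature: abrupt, localized, often directionally
structured changes in image texture (microcalcification clusters, exudate
rings, high-contrast lesions). `texdirect` implements a feature-extraction
chain built on exactly that signature, with a classical statistical
classifier on top, for researchers who want a simple, auditable,
segmentation-free baseline for whole-image screening.

## Method

1. **Wavelet step.** A separable 2-D discrete wavelet decomposition
   (Daubechies-4, 8 taps) splits the image into LL/LH/HL/HH subbands at
   half resolution; the **HH** detail subband — high-pass in both
   directions — isolates abrupt texture changes while discarding the smooth
   anatomical background. Levels 1 and 2 (recursing on LL) are supported.
2. **Gabor step.** A bank of 12 real Gabor kernels,

   `G(x, y) = exp(-((x'/σx)² + (y'/σy)²)/2) · cos(2π f x')`,
   `x' = x cosθ + y sinθ`, `y' = y cosθ − x sinθ`,

   over 4 orientations θ ∈ {0, π/4, π/2, 3π/4} and 3 central frequencies
   f ∈ {2, 2.5, 3} cycles/pixel, is convolved with the HH subband,
   resolving its high-frequency content by direction.
3. **Features.** For each filtered image the coefficient distribution p(z)
   is estimated on 256 equal-width bins and summarized by entropy
   `E = −Σ p log₂ p` and uniformity `U = Σ p²`, giving a 24-component
   vector `[E₁..E₁₂, U₁..U₁₂]` (or `[E, U]` for the wavelet-only mode).
4. **Classifier.** A soft-margin SVM with the inhomogeneous polynomial
   kernel `K(x, xᵢ) = (⟨xᵢ, x⟩ + 1)²` (C = 1), evaluated under stratified
   tenfold or leave-one-out cross-validation; reported as correct
   classification rate (CCR), sensitivity (true-positive rate on abnormal)
   and specificity (true-negative rate on normal), mean ± sd over folds.

Three feature modes are built in for controlled comparison on identical
folds: `dwt` (HH entropy/uniformity alone), `dwt_gabor` (the hybrid chain
above), and `gabor` (the bank applied to the raw image, no wavelet step).

A seeded synthetic generator provides labeled data emulating the target
structure — smooth blurred-noise backgrounds for "normal", plus hard-edged
bright discs and an oriented streak for "abnormal" — so the whole pipeline
is testable without clinical image downloads.

## Worked example

```python
import texdirect as td

model = td.TextureClassificationModel.from_synthetic()   # 40 normal + 40 abnormal
res = model.fit(protocol="tenfold", seed=0)
print(res.summary())
```

```text
Texture screening cross-validation
==================================================
mode: dwt_gabor    DWT level: 1
wavelet: db4 (symmetric)   bank: 3x4   bins: 256
SVM: poly degree 2, C = 1.0
protocol: tenfold   seed: 0   n = 80
--------------------------------------------------
CCR          100.00% (+/- 0.00)   pooled 100.00%
sensitivity  100.00% (+/- 0.00)   pooled 100.00%
specificity  100.00% (+/- 0.00)   pooled 100.00%
```

Under the default synthetic conditions the anomalies dominate the HH
subband and every fold classifies perfectly. The modes separate in harder
regimes; with barely-raised anomalies on very smooth backgrounds
(`td.subtle_anomaly_config()`), the Gabor-only baseline collapses while
the hybrid features do not:

```python
images, labels, ids = td.generate_dataset(td.subtle_anomaly_config())
print(td.compare_modes(images, labels, ids, levels=(1,), seed=0)
      [["mode", "ccr_mean", "sensitivity_mean", "specificity_mean"]])
```

```text
     mode  ccr_mean  sensitivity_mean  specificity_mean
      dwt      1.00              1.00              1.00
dwt_gabor      1.00              1.00              1.00
    gabor      0.55              0.25              0.85
```

Read: the raw-image Gabor features miss 75% of the abnormal images
(sensitivity 0.25) while flagging most normals correctly — a one-sided
failure — whereas features drawn from the HH subband keep both rates at
100% on the same folds.

From a shell, the same experiments are:

```sh
texdirect run --out out/           # default hybrid experiment
texdirect compare --out out/       # all modes, shared folds
texdirect synth --out data/        # write the synthetic images as PNGs
```

Each run directory contains the resolved config, the feature table, the
per-fold metrics, a JSON summary and a log of every analysis knob.

## Documentation

`docs/methods.md` describes the model, parameter choices, the synthetic
data's scope and limits, and numerical conventions.
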