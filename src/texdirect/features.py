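"""Entropy/uniformity texture descriptors over coefficient histograms.

The descriptors treat a coefficient image purely as a sample of a scalar
random variable z: the empirical distribution p(z) is estimated by relative
frequency over equal-width bins, and two summary statistics are computed,

    E = -sum p(z) log2 p(z)      (entropy, bits; texture disorder)
    U =  sum p(z)^2              (uniformity; 1 for constant, 1/k for flat)

Binning spans the per-image [min, max] of the coefficients, which makes both
statistics invariant to positive rescaling of the image and to any spatial
permutation of its pixels.  The default of 256 bins mirrors the 8-bit
gray-level convention of the texture literature.

Three feature modes assemble the classifier inputs:

* ``DWT``       - [E, U] of the HH subband at the requested level.
* ``DWT_GABOR`` - the HH subband is passed through the 12-filter Gabor bank
                  and [E1..E12, U1..U12] is collected in bank order.
* ``GABOR``     - the bank applied to the raw image (no wavelet step), same
                  24-component layout; the single-transform baseline.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np

from .exceptions import ValidationError
from .gabor import FilterBankConfig, apply_bank
from .io import as_image_matrix
from .wavelet import WaveletSpec, extract_hh

DEFAULT_N_BINS = 256


class FeatureMode(str, Enum):
    """Which transform chain produces the coefficients to summarize."""

    DWT = "dwt"
    GABOR = "gabor"
    DWT_GABOR = "dwt_gabor"


@dataclass(frozen=True)
class ProbabilityHistogram:
    """Equal-width-bin estimate of the coefficient distribution p(z)."""

    bin_edges: np.ndarray
    pmf: np.ndarray

    def __post_init__(self):
        edges = np.asarray(self.bin_edges, dtype=np.float64)
        pmf = np.asarray(self.pmf, dtype=np.float64)
        object.__setattr__(self, "bin_edges", edges)
        object.__setattr__(self, "pmf", pmf)
        if pmf.size != edges.size - 1:
            raise ValidationError("need exactly one more edge than bins")
        if np.any(np.diff(edges) <= 0):
            raise ValidationError("bin edges must be strictly increasing")
        if np.any(pmf < 0) or abs(pmf.sum() - 1.0) > 1e-12:
            raise ValidationError("pmf must be non-negative and sum to 1")

    @property
    def n_bins(self) -> int:
        return int(self.pmf.size)


def estimate_pmf(coeffs: np.ndarray, n_bins: int = DEFAULT_N_BINS) -> ProbabilityHistogram:
    """Relative-frequency histogram over [min, max] of the coefficients.

    A constant array has no spread to bin and degenerates to a single bin
    carrying all mass; spread below 1e-12 (relative to the coefficient
    magnitude) is treated as constant so that numerically-annihilated
    subbands (e.g. HH of a flat image) are recognized as degenerate.
    """
    arr = np.asarray(coeffs, dtype=np.float64).ravel()
    if arr.size == 0:
        raise ValidationError("cannot estimate a distribution from no coefficients")
    if not np.all(np.isfinite(arr)):
        raise ValidationError("coefficients contain non-finite values")
    if n_bins < 2:
        raise ValidationError("n_bins must be >= 2")
    lo, hi = float(arr.min()), float(arr.max())
    if hi - lo <= 1e-12 * max(1.0, abs(lo), abs(hi)):
        return ProbabilityHistogram(bin_edges=np.array([lo - 0.5, lo + 0.5]),
                                    pmf=np.array([1.0]))
    counts, edges = np.histogram(arr, bins=n_bins, range=(lo, hi))
    return ProbabilityHistogram(bin_edges=edges, pmf=counts / arr.size)


def entropy(hist: ProbabilityHistogram) -> float:
    """Shannon entropy -sum p log2 p in bits, with 0 log 0 := 0."""
    p = hist.pmf[hist.pmf > 0]
    return float(-(p * np.log2(p)).sum())


def uniformity(hist: ProbabilityHistogram) -> float:
    """Energy sum p^2; lies in [1/n_bins, 1]."""
    return float((hist.pmf ** 2).sum())


@dataclass(frozen=True)
class FeatureVector:
    """Ordered descriptor values for one image under one feature mode.

    Length 2 ([E, U]) for DWT mode; 24 ([E1..E12, U1..U12] in bank
    enumeration order) for the Gabor-based modes with the default bank.
    """

    mode: FeatureMode
    values: np.ndarray
    names: tuple[str, ...]
    level: int | None = None

    def __post_init__(self):
        vals = np.asarray(self.values, dtype=np.float64)
        object.__setattr__(self, "values", vals)
        if vals.size != len(self.names):
            raise ValidationError("values and names must align")
        if self.mode is FeatureMode.DWT and vals.size != 2:
            raise ValidationError("DWT mode produces exactly [E, U]")
        if self.mode is not FeatureMode.GABOR and self.level is None:
            raise ValidationError("DWT-based modes require a decomposition level")

    def __len__(self) -> int:
        return int(self.values.size)


def _entropy_uniformity(coeffs: np.ndarray, n_bins: int) -> tuple[float, float]:
    hist = estimate_pmf(coeffs, n_bins)
    return entropy(hist), uniformity(hist)


def build_feature_vector(image: np.ndarray, mode: FeatureMode | str,
                         level: int | None = None,
                         wavelet: WaveletSpec | None = None,
                         bank: FilterBankConfig | None = None,
                         n_bins: int = DEFAULT_N_BINS) -> FeatureVector:
    """Extract the descriptor vector for one image under the chosen mode."""
    mode = FeatureMode(mode)
    img = as_image_matrix(image)
    if mode is FeatureMode.DWT:
        if level is None:
            raise ValidationError("DWT mode requires a level")
        e, u = _entropy_uniformity(extract_hh(img, level, wavelet), n_bins)
        return FeatureVector(mode=mode, values=np.array([e, u]),
                             names=("E", "U"), level=level)

    bank = bank or FilterBankConfig()
    if mode is FeatureMode.DWT_GABOR:
        if level is None:
            raise ValidationError("DWT_GABOR mode requires a level")
        carrier = extract_hh(img, level, wavelet)
    else:
        carrier = img
        level = None
    responses = apply_bank(carrier, bank)
    pairs = [_entropy_uniformity(r, n_bins) for r in responses]
    values = np.array([e for e, _ in pairs] + [u for _, u in pairs])
    labels = bank.labels()
    names = tuple(f"E_{l}" for l in labels) + tuple(f"U_{l}" for l in labels)
    return FeatureVector(mode=mode, values=values, names=names, level=level)


def feature_table(images, labels, ids, mode: FeatureMode | str,
                  level: int | None = None, wavelet: WaveletSpec | None = None,
                  bank: FilterBankConfig | None = None,
                  n_bins: int = DEFAULT_N_BINS):
    """Per-image feature matrix as a pandas DataFrame (id, label, features)."""
    import pandas as pd

    vectors = [build_feature_vector(img, mode, level, wavelet, bank, n_bins)
               for img in images]
    frame = pd.DataFrame([v.values for v in vectors], columns=list(vectors[0].names))
    frame.insert(0, "label", np.asarray(labels))
    frame.insert(0, "image_id", list(ids))
    return frame
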