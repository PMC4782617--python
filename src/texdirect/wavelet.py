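"""Separable 2-D discrete wavelet decomposition and HH-subband extraction.

One analysis level splits an image into the four standard subbands: the
approximation LL and the detail subbands LH (low-pass horizontally, high-pass
vertically), HL, and HH (high-pass in both directions).  The HH subband
carries diagonal high-frequency content — the abrupt local intensity changes
that distinguish anomalous from smooth tissue texture — and is the carrier
signal for the downstream Gabor analysis.

The transform is implemented directly as row-then-column filtering with
dyadic decimation so that the boundary handling is explicit and configurable:

* ``symmetric`` (default): half-sample mirror extension, the natural choice
  for photographic/medical content with no periodic structure.  Each subband
  dimension is ``ceil(parent / 2)``.
* ``periodization``: periodic extension; for even parents each subband
  dimension is exactly ``parent / 2`` and the output matches
  ``pywt.dwt2(..., mode="periodization")`` to machine precision (asserted in
  the test suite).

The decimation phase is fixed at ``L/2`` (``L`` = filter length): subband
sample ``k`` is the boundary-extended convolution evaluated at position
``2k + L/2``.  The default wavelet is Daubechies-4 in the 4-vanishing-moment
(8-tap) sense; filter taps are taken from PyWavelets.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pywt
from scipy.signal import convolve

from .exceptions import DimensionError, ValidationError
from .io import as_image_matrix

_BOUNDARY_MODES = {"symmetric": "symmetric", "periodization": "wrap"}


@dataclass(frozen=True)
class WaveletSpec:
    """An analysis filter pair (quadrature low/high pass) plus boundary rule.

    Parameters
    ----------
    name : str
        Identifier of the wavelet family member, e.g. ``"db4"``.
    lowpass, highpass : ndarray
        Decomposition impulse responses g(n) and h(n).  The low-pass taps
        must sum to sqrt(2) and the high-pass taps to 0 (quadrature pair).
    boundary_mode : {"symmetric", "periodization"}
        Signal extension rule applied before filtering.
    """

    name: str
    lowpass: np.ndarray
    highpass: np.ndarray
    boundary_mode: str = "symmetric"

    def __post_init__(self):
        lo = np.asarray(self.lowpass, dtype=np.float64)
        hi = np.asarray(self.highpass, dtype=np.float64)
        object.__setattr__(self, "lowpass", lo)
        object.__setattr__(self, "highpass", hi)
        if lo.ndim != 1 or hi.ndim != 1 or lo.size != hi.size:
            raise ValidationError("filter taps must be 1-D sequences of equal length")
        if abs(lo.sum() - np.sqrt(2.0)) > 1e-10:
            raise ValidationError("low-pass taps must sum to sqrt(2)")
        if abs(hi.sum()) > 1e-10:
            raise ValidationError("high-pass taps must sum to 0")
        if self.boundary_mode not in _BOUNDARY_MODES:
            raise ValidationError(f"unknown boundary mode {self.boundary_mode!r}")

    @classmethod
    def from_name(cls, name: str = "db4", boundary_mode: str = "symmetric") -> "WaveletSpec":
        """Build a spec from a PyWavelets family name (default Daubechies-4)."""
        w = pywt.Wavelet(name)
        return cls(name=name, lowpass=np.asarray(w.dec_lo), highpass=np.asarray(w.dec_hi),
                   boundary_mode=boundary_mode)

    @property
    def filter_length(self) -> int:
        return int(self.lowpass.size)


@dataclass(frozen=True)
class SubbandSet:
    """The four subimages of one decomposition level (equal dimensions)."""

    level: int
    ll: np.ndarray
    lh: np.ndarray
    hl: np.ndarray
    hh: np.ndarray

    def __post_init__(self):
        shapes = {b.shape for b in (self.ll, self.lh, self.hl, self.hh)}
        if len(shapes) != 1:
            raise ValidationError(f"subband dimensions differ: {shapes}")
        if self.level < 1:
            raise ValidationError("level must be >= 1")

    @property
    def shape(self):
        return self.ll.shape


def _filter_downsample(arr: np.ndarray, filt: np.ndarray, mode: str) -> np.ndarray:
    """Convolve along the last axis under the boundary rule, keep every other
    sample at phase L/2; output length is ceil(n / 2)."""
    n = arr.shape[-1]
    L = filt.size
    pad = [(0, 0)] * (arr.ndim - 1) + [(L, L)]
    ext = np.pad(arr, pad, mode=_BOUNDARY_MODES[mode])
    shape = (1,) * (arr.ndim - 1) + (L,)
    full = convolve(ext, filt.reshape(shape), mode="valid")
    idx = 2 * np.arange((n + 1) // 2) + L // 2 + 1
    return full[..., idx]


def decompose_once(image: np.ndarray, wavelet: WaveletSpec | None = None) -> SubbandSet:
    """One analysis level: filter/decimate rows, then columns of each result.

    Returns the four subbands; ``hh`` is high-pass in both directions, so any
    constant image yields an identically-zero HH (the high-pass taps sum to
    zero).
    """
    img = as_image_matrix(image)
    wavelet = wavelet or WaveletSpec.from_name()
    L = wavelet.filter_length
    if min(img.shape) < L:
        raise DimensionError(
            f"image {img.shape} smaller than filter support ({L} taps)")
    mode = wavelet.boundary_mode
    # rows first (filter along x), then columns of each half-width result
    lo_x = _filter_downsample(img, wavelet.lowpass, mode)
    hi_x = _filter_downsample(img, wavelet.highpass, mode)
    ll = _filter_downsample(lo_x.T, wavelet.lowpass, mode).T
    lh = _filter_downsample(lo_x.T, wavelet.highpass, mode).T
    hl = _filter_downsample(hi_x.T, wavelet.lowpass, mode).T
    hh = _filter_downsample(hi_x.T, wavelet.highpass, mode).T
    return SubbandSet(level=1, ll=ll, lh=lh, hl=hl, hh=hh)


def extract_hh(image: np.ndarray, level: int, wavelet: WaveletSpec | None = None,
               allow_deep: bool = False) -> np.ndarray:
    """HH detail subband after ``level`` pyramid steps.

    Level 2 recurses on the level-1 approximation LL (standard Mallat
    pyramid), then takes HH.  Levels above 2 are outside the evaluated range
    and require ``allow_deep=True``.
    """
    if level < 1 or (level > 2 and not allow_deep):
        raise ValidationError(f"level must be 1 or 2 (got {level})")
    wavelet = wavelet or WaveletSpec.from_name()
    current = as_image_matrix(image)
    for _ in range(level - 1):
        current = decompose_once(current, wavelet).ll
    return decompose_once(current, wavelet).hh
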