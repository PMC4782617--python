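"""Real-part Gabor kernels and a 12-filter (4 orientations x 3 frequencies) bank.

A Gabor filter is a sinusoid modulated by an elliptical Gaussian envelope;
its real part responds selectively to intensity oscillations at a central
spatial frequency ``f`` along orientation ``theta``.  The kernel sampled at
integer pixel offsets (x, y) from its center is

    G(x, y) = exp(-0.5 * ((x'/sx)^2 + (y'/sy)^2)) * cos(2 pi f x')

with the rotated coordinates

    x' = x cos(theta) + y sin(theta),   y' = y cos(theta) - x sin(theta).

``f`` is expressed in cycles per pixel of the sampling grid, taken literally;
the default bank frequencies {2, 2.5, 3} therefore alias on the integer
lattice by design — the resulting kernels are what the entropy/uniformity
features are computed from, not a band-pass analysis in the signal-processing
sense.  A ``frequency_scale`` knob rescales all bank frequencies for users
who want sub-Nyquist responses.

Only the real part is produced; the imaginary quadrature component is a
documented extension point, not implemented.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .exceptions import ValidationError
from .io import as_image_matrix

#: Full width at half maximum of a unit-variance Gaussian: 2*sqrt(2*ln 2).
FWHM_PER_SIGMA = 2.0 * math.sqrt(2.0 * math.log(2.0))


def rotate_coords(x, y, theta):
    """Rotate pixel offsets into the filter frame.

    Returns ``(x cos(theta) + y sin(theta), y cos(theta) - x sin(theta))``;
    the transform is norm-preserving.
    """
    c, s = math.cos(theta), math.sin(theta)
    return x * c + y * s, y * c - x * s


@dataclass(frozen=True)
class GaborParams:
    """The (sigma_x, sigma_y, f, theta) quadruple of one filter.

    sigma_x, sigma_y : Gaussian spreads along the rotated axes, in pixels.
    frequency : central frequency f, in cycles per pixel.
    theta : orientation in radians; the real kernel has period pi in theta.
    """

    sigma_x: float
    sigma_y: float
    frequency: float
    theta: float

    def __post_init__(self):
        for name in ("sigma_x", "sigma_y", "frequency"):
            v = getattr(self, name)
            if not (np.isfinite(v) and v > 0):
                raise ValidationError(f"{name} must be a positive finite number, got {v}")
        if not np.isfinite(self.theta):
            raise ValidationError("theta must be finite")

    @property
    def canonical_theta(self) -> float:
        """Orientation reduced to [0, pi)."""
        return self.theta % math.pi


@dataclass(frozen=True)
class GaborKernel:
    """An odd-sized square grid of real filter weights; weight 1 at center."""

    weights: np.ndarray
    params: GaborParams

    def __post_init__(self):
        w = np.asarray(self.weights, dtype=np.float64)
        object.__setattr__(self, "weights", w)
        side = w.shape[0]
        if w.ndim != 2 or w.shape[0] != w.shape[1] or side % 2 == 0 or side < 3:
            raise ValidationError(f"kernel must be square and odd-sized >= 3, got {w.shape}")
        if not np.all(np.isfinite(w)):
            raise ValidationError("kernel contains non-finite weights")

    @property
    def half_width(self) -> int:
        return self.weights.shape[0] // 2

    @property
    def center(self) -> tuple[int, int]:
        """Index of the (x, y) = (0, 0) sample."""
        return (self.half_width, self.half_width)


def gabor_kernel_real(params: GaborParams, truncation_nsigma: float = 3.0) -> GaborKernel:
    """Sample the real Gabor formula on an odd square grid.

    The half-width is ``max(3, ceil(truncation_nsigma * max(sigma_x,
    sigma_y)))``; a 3-sigma support keeps > 99% of the Gaussian envelope
    mass.  ``weights[r, c]`` holds the sample at offsets ``y = r - h``
    (row, downward) and ``x = c - h`` (column, rightward).
    """
    if truncation_nsigma <= 0:
        raise ValidationError("truncation_nsigma must be positive")
    h = max(3, math.ceil(truncation_nsigma * max(params.sigma_x, params.sigma_y)))
    y, x = np.mgrid[-h:h + 1, -h:h + 1].astype(np.float64)
    xr, yr = rotate_coords(x, y, params.theta)
    envelope = np.exp(-0.5 * ((xr / params.sigma_x) ** 2 + (yr / params.sigma_y) ** 2))
    weights = envelope * np.cos(2.0 * math.pi * params.frequency * xr)
    return GaborKernel(weights=weights, params=params)


def apply_filter(image: np.ndarray, kernel: GaborKernel) -> np.ndarray:
    """True 2-D convolution (kernel flipped) with symmetric boundary padding.

    Output has the same shape as the input.  For the even-symmetric kernels
    produced here convolution and correlation coincide, but the contract is
    convolution.
    """
    img = as_image_matrix(image)
    return ndimage.convolve(img, kernel.weights[::-1, ::-1], mode="reflect")


@dataclass(frozen=True)
class FilterBankConfig:
    """Enumeration of the (f, theta) grid plus the shared sigma scheme.

    Defaults follow the evaluated bank: orientations {0, pi/4, pi/2, 3pi/4}
    covering both axes and both diagonals, frequencies {2, 2.5, 3} cycles per
    pixel, and unit sigmas.  ``mammogram`` builds the alternative anisotropic
    scheme sigma_x = tau / 2.35 (tau = Gaussian FWHM in pixels), sigma_y =
    8 sigma_x, used for mammographic textures.

    The bank order is frequency-major (f ascending as listed), orientation-
    minor; output index i of :func:`apply_bank` is feature subscript i+1.
    """

    orientations: tuple[float, ...] = (0.0, math.pi / 4, math.pi / 2, 3 * math.pi / 4)
    frequencies: tuple[float, ...] = (2.0, 2.5, 3.0)
    sigma_x: float = 1.0
    sigma_y: float = 1.0
    truncation_nsigma: float = 3.0
    frequency_scale: float = 1.0

    def __post_init__(self):
        if len(self.orientations) == 0 or len(self.frequencies) == 0:
            raise ValidationError("orientations and frequencies must be non-empty")
        if self.frequency_scale <= 0:
            raise ValidationError("frequency_scale must be positive")

    @classmethod
    def mammogram(cls, tau: float = 2.35, **kwargs) -> "FilterBankConfig":
        """Anisotropic sigma scheme: sigma_x = tau/2.35, sigma_y = 8 sigma_x."""
        sx = tau / 2.35
        return cls(sigma_x=sx, sigma_y=8.0 * sx, **kwargs)

    @property
    def size(self) -> int:
        return len(self.orientations) * len(self.frequencies)

    def params(self) -> list[GaborParams]:
        """The bank's parameter quadruples in enumeration order."""
        return [
            GaborParams(sigma_x=self.sigma_x, sigma_y=self.sigma_y,
                        frequency=f * self.frequency_scale, theta=t)
            for f in self.frequencies
            for t in self.orientations
        ]

    def kernels(self) -> list[GaborKernel]:
        return [gabor_kernel_real(p, self.truncation_nsigma) for p in self.params()]

    def labels(self) -> list[str]:
        """Stable per-filter labels, e.g. ``f2.0_t0.00`` (theta in radians)."""
        return [f"f{f:g}_t{t:.2f}" for f in self.frequencies for t in self.orientations]


def apply_bank(image: np.ndarray, config: FilterBankConfig | None = None) -> list[np.ndarray]:
    """Filter the image with every kernel of the bank, in enumeration order."""
    config = config or FilterBankConfig()
    img = as_image_matrix(image)
    return [apply_filter(img, k) for k in config.kernels()]
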