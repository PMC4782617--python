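"""Seeded generator of labeled synthetic images for the screening task.

The generator emulates the minimal structure the method claims to exploit.
"Normal" images are smooth low-frequency textures: unit-range-normalized
Gaussian-blurred white noise, standing in for healthy tissue with gradual
intensity variation.  "Abnormal" images add localized high-frequency,
high-contrast content to the same kind of background:

* hard-edged bright discs — the small-bright-spot archetype of clustered or
  scattered calcifications and retinal exudates;
* optionally one bright oriented line segment (a "streak"), exercising the
  directional selectivity of the filter bank.

Every image is a pure function of ``(config, index)``: the background and
the anomaly geometry draw from independent, explicitly derived random
streams, so an abnormal image with zero anomaly amplitude is pixel-identical
to the normal image of the same index.

Default parameters (128 x 128 images, 40 per class, blur scale 4 px, six
discs of radius 2 at amplitude 0.25, one diagonal streak) were chosen so
that the anomalies carry clear high-frequency (HH-subband) energy above the
background while remaining small against the background's own contrast —
a separable but non-trivial screening problem.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .exceptions import ValidationError

_NORMAL_STREAM, _ABNORMAL_STREAM = 0, 1
_BORDER = 4  # anomaly centers keep this many pixels clear of the edge


@dataclass(frozen=True)
class SyntheticConfig:
    """All knobs of the generator; generation is a pure function of this.

    image_size : (H, W) pixels.
    n_per_class : images per label; the dataset is balanced by construction.
    background_smoothness : Gaussian blur sigma (px) of the base noise field.
    spot_count / spot_radius / spot_amplitude : disc anomalies per abnormal
        image, their radius (px) and added intensity (clipped to 1).
    streak_enabled / streak_angle : one bright line segment at the given
        angle (radians), drawn at the spot amplitude.
    seed : root of every random stream used.
    """

    image_size: tuple[int, int] = (128, 128)
    n_per_class: int = 40
    background_smoothness: float = 4.0
    spot_count: int = 6
    spot_radius: int = 2
    spot_amplitude: float = 0.25
    streak_enabled: bool = True
    streak_angle: float = math.pi / 4
    seed: int = 7

    def __post_init__(self):
        h, w = self.image_size
        if h < 8 or w < 8:
            raise ValidationError("image_size must be at least 8 x 8")
        if not (0.0 <= self.spot_amplitude <= 1.0):
            raise ValidationError("spot_amplitude must lie in [0, 1]")
        if self.spot_radius < 1 or self.spot_count < 0 or self.n_per_class < 0:
            raise ValidationError("radius >= 1 and counts >= 0 required")
        if self.background_smoothness <= 0:
            raise ValidationError("background_smoothness must be positive")


def _rng(config: SyntheticConfig, stream: int, index: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([config.seed, stream, index]))


def generate_normal(config: SyntheticConfig, index: int) -> np.ndarray:
    """Smooth background texture: blurred white noise scaled to [0, 1]."""
    rng = _rng(config, _NORMAL_STREAM, index)
    noise = rng.standard_normal(config.image_size)
    smooth = ndimage.gaussian_filter(noise, sigma=config.background_smoothness)
    lo, hi = smooth.min(), smooth.max()
    if hi == lo:  # blurred noise is flat only in pathological configs
        return np.full(config.image_size, 0.5)
    return (smooth - lo) / (hi - lo)


def generate_abnormal(config: SyntheticConfig, index: int) -> np.ndarray:
    """Background of the same index plus seeded discs and optional streak."""
    h, w = config.image_size
    r = config.spot_radius
    margin = _BORDER + r
    if 2 * margin >= min(h, w):
        raise ValidationError(
            f"spot radius {r} plus border does not fit in {config.image_size}")
    img = generate_normal(config, index).copy()
    rng = _rng(config, _ABNORMAL_STREAM, index)
    yy, xx = np.mgrid[0:h, 0:w]
    for _ in range(config.spot_count):
        cy = rng.integers(margin, h - margin)
        cx = rng.integers(margin, w - margin)
        disc = (yy - cy) ** 2 + (xx - cx) ** 2 <= r ** 2
        img[disc] += config.spot_amplitude
    if config.streak_enabled:
        length = min(h, w) // 3
        cy = int(rng.integers(margin + length // 2, h - margin - length // 2))
        cx = int(rng.integers(margin + length // 2, w - margin - length // 2))
        dy, dx = math.sin(config.streak_angle), math.cos(config.streak_angle)
        pixels = {(int(round(cy + t * dy)), int(round(cx + t * dx)))
                  for t in np.linspace(-length / 2, length / 2, 2 * length)}
        for py, px in pixels:
            if 0 <= py < h and 0 <= px < w:
                img[py, px] += config.spot_amplitude
    return np.clip(img, 0.0, 1.0)


def subtle_anomaly_config(seed: int = 11) -> SyntheticConfig:
    """A regime where single-transform (raw-image Gabor) features fail.

    Very smooth backgrounds (blur sigma 16 px) with barely-raised discs
    (amplitude 0.001, no streak): the anomalies sit far below the
    background's own contrast, so entropy/uniformity of Gabor responses to
    the raw image carry almost no class signal and the classifier degenerates
    toward one class, while the same anomalies still dominate the
    near-silent HH subband and remain separable for the hybrid features.
    """
    return SyntheticConfig(background_smoothness=16.0, spot_amplitude=0.001,
                           streak_enabled=False, n_per_class=20, seed=seed)


def generate_dataset(config: SyntheticConfig):
    """Balanced labeled set: n normal (-1) then n abnormal (+1).

    Returns ``(images, labels, ids)`` with stable per-image identifiers.
    """
    if config.n_per_class < 1:
        raise ValidationError("n_per_class must be >= 1")
    images, labels, ids = [], [], []
    for i in range(config.n_per_class):
        images.append(generate_normal(config, i))
        labels.append(-1)
        ids.append(f"normal_{i:03d}")
    for i in range(config.n_per_class):
        images.append(generate_abnormal(config, config.n_per_class + i))
        labels.append(+1)
        ids.append(f"abnormal_{i:03d}")
    return images, np.asarray(labels), ids
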