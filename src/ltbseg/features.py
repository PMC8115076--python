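"""Scalar image features consumed by the one-stage observer models.

The one-stage models reduce a stimulus to three numbers: the absolute
luminance differences across the right-oblique and left-oblique diagonals
(``L_R``, ``L_L``) and the global RMS contrast ``C``.  Differences are taken
between the *means* of the two half-disc pixel populations, so the feature
scale is independent of image size (any residual scale choice is absorbed by
the model gain).  RMS contrast is computed over the disc interior only; the
constant background would otherwise dilute it by an arbitrary factor.

Pixels lying exactly on a diagonal belong to neither half of that diagonal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ltbseg.stimulus import StimulusImage, diagonal_coords


@dataclass(frozen=True)
class FeatureVector:
    """Diagonal luminance differences and RMS contrast of one stimulus."""

    L_R: float  #: |mean luminance difference| across the right-oblique diagonal
    L_L: float  #: same across the left-oblique diagonal
    C: float = 0.0  #: global RMS contrast (SD / mean over the disc)


def _half_mean_diff(pixels: np.ndarray, mask: np.ndarray, d: np.ndarray) -> float:
    pos = mask & (d > 0)
    neg = mask & (d < 0)
    return abs(float(pixels[pos].mean()) - float(pixels[neg].mean()))


def luminance_diffs(image: StimulusImage) -> FeatureVector:
    """Absolute half-disc mean-luminance differences across both diagonals.

    Raises ``ValueError`` on an empty disc mask.
    """
    mask = image.disc_mask
    if not mask.any():
        raise ValueError("stimulus has an empty disc mask")
    d_right, d_left = diagonal_coords(image.image_size)
    return FeatureVector(
        L_R=_half_mean_diff(image.pixels, mask, d_right),
        L_L=_half_mean_diff(image.pixels, mask, d_left),
    )


def rms_contrast(image: StimulusImage) -> float:
    """RMS contrast over the disc interior: SD / mean of masked pixels."""
    vals = image.pixels[image.disc_mask]
    if vals.size == 0:
        raise ValueError("stimulus has an empty disc mask")
    mean = float(vals.mean())
    if mean <= 0.0:
        raise ValueError("mean luminance over the disc is zero")
    return float(vals.std()) / mean


def measure(image: StimulusImage) -> FeatureVector:
    """Full feature vector: both diagonal differences plus RMS contrast."""
    lv = luminance_diffs(image)
    return FeatureVector(L_R=lv.L_R, L_L=lv.L_L, C=rms_contrast(image))
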