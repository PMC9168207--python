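"""Separable 2-D discrete wavelet features.

A 3-level db4 decomposition with periodization (so level-l sub-bands are
exactly (512 / 2^l) squared), each of the 10 sub-bands block-averaged in
absolute value to 16x16 and concatenated coarse -> fine: 10 x 256 = 2560
features.
"""

from __future__ import annotations

import numpy as np
import pywt

from .base import BaseImageFeatureExtractor, Subband, SubbandSet, block_average

DEFAULT_WAVELET = "db4"
POOL_SHAPE = (16, 16)


def dwt_decompose(image, levels: int = 3, wavelet: str = DEFAULT_WAVELET) -> SubbandSet:
    """Multi-level 2-D DWT with periodic boundary handling.

    Returns sub-bands ordered coarse -> fine: approximation first, then
    (H, V, D) detail triplets from the deepest level up.
    """
    img = np.asarray(getattr(image, "pixels", image), dtype=float)
    if levels < 1:
        raise ValueError("levels must be >= 1")
    n = min(img.shape)
    if n % (2**levels) or 2**levels > n:
        raise ValueError("levels too deep for image size")
    coeffs = pywt.wavedec2(img, wavelet, mode="periodization", level=levels)
    bands = [Subband(coeffs=coeffs[0], scale=0, orientation=0, tag=f"A{levels}")]
    for i, detail in enumerate(coeffs[1:]):
        level = levels - i  # deepest (coarsest) detail first
        for orient, (name, c) in enumerate(zip("HVD", detail)):
            bands.append(
                Subband(coeffs=c, scale=levels - level + 1, orientation=orient, tag=f"{name}{level}")
            )
    return SubbandSet(transform_name="dwt", subbands=bands)


class DWTFeatures(BaseImageFeatureExtractor):
    """3-level db4 DWT, |coefficients| block-averaged to 16x16 per band."""

    method = "dwt"
    n_features = 2560

    def __init__(self, levels: int = 3, wavelet: str = DEFAULT_WAVELET):
        self.levels = levels
        self.wavelet = wavelet

    def _extract(self, image: np.ndarray) -> np.ndarray:
        bands = dwt_decompose(image, levels=self.levels, wavelet=self.wavelet)
        return np.concatenate(
            [block_average(np.abs(b.coeffs), POOL_SHAPE).ravel() for b in bands]
        )


def dwt_features(image) -> np.ndarray:
    """Length-2560 DWT feature vector of a 512x512 image."""
    return DWTFeatures().extract(image)
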