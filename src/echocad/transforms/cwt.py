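"""2-D continuous wavelet (Mexican-hat) features.

The image is convolved (frequency-domain product) with an isotropic
Mexican-hat / Laplacian-of-Gaussian wavelet at 8 dyadic scales
{1, 2, 4, ..., 128} px.  The analyzing function is zero-mean, so constant
images give zero response.  Each |response| map is block-averaged to 32x32:
8 x 1024 = 8192 features.
"""

from __future__ import annotations

import numpy as np

from .base import BaseImageFeatureExtractor, block_average

POOL_SHAPE = (32, 32)
DEFAULT_SCALES = (1, 2, 4, 8, 16, 32, 64, 128)


def mexican_hat_kernel_fft(shape: tuple[int, int], scale: float) -> np.ndarray:
    """Frequency response of the Mexican-hat wavelet at ``scale``.

    This is the scale-normalized Laplacian-of-Gaussian (response amplitude
    is scale-invariant, so the strongest response across scales picks out
    structures of matching size).
    """
    wy = 2 * np.pi * np.fft.fftfreq(shape[0])[:, None]
    wx = 2 * np.pi * np.fft.fftfreq(shape[1])[None, :]
    w2 = (scale**2) * (wx**2 + wy**2)
    return w2 * np.exp(-w2 / 2.0)


def cwt2d_response(image: np.ndarray, scale: float) -> np.ndarray:
    """Wavelet response map at one scale (same shape as the input)."""
    image = np.asarray(getattr(image, "pixels", image), dtype=float)
    spectrum = np.fft.fft2(image)
    return np.fft.ifft2(spectrum * mexican_hat_kernel_fft(image.shape, scale)).real


class CWT2DFeatures(BaseImageFeatureExtractor):
    """Mexican-hat responses at 8 dyadic scales, pooled to 32x32 (length 8192)."""

    method = "cwt"
    n_features = 8192

    def __init__(self, scales: tuple[int, ...] = DEFAULT_SCALES):
        self.scales = scales

    def _extract(self, image: np.ndarray) -> np.ndarray:
        spectrum = np.fft.fft2(image)
        feats = []
        for s in self.scales:
            resp = np.fft.ifft2(spectrum * mexican_hat_kernel_fft(image.shape, s)).real
            feats.append(block_average(np.abs(resp), POOL_SHAPE).ravel())
        return np.concatenate(feats)


def cwt2d_features(image) -> np.ndarray:
    """Length-8192 Mexican-hat wavelet feature vector of a 512x512 image."""
    return CWT2DFeatures().extract(image)
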