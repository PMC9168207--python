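"""Cone-adapted discrete shearlet features.

The 2-D frequency plane is split into a low-frequency disk and two cones
(horizontal: |w1| >= |w2|, vertical: |w2| > |w1|).  Within each cone, Meyer
raised-cosine windows in the shear (slope) coordinate select 5 orientations
(shears k = -2..2) per scale, multiplied by dyadic Meyer radial band windows
(3 scales).  The squared filter magnitudes sum to 1 at every frequency point
(a tight frame): 1 low-pass + 3 scales x 2 cones x 5 shears = 31 filters.

Features: each of the 31 coefficient maps (512x512) is block-averaged in
absolute value to 16x32 (512 values) -> 31 x 512 = 15872 features, ordered
low-pass first, then scale-major, cone-major (horizontal first), shear
ascending.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np

from .base import BaseImageFeatureExtractor, block_average

POOL_SHAPE = (16, 32)
N_SCALES = 3
MAX_SHEAR = 2


def _radial_partition(r: np.ndarray, scales: int) -> list[np.ndarray]:
    """Squared-window radial partition of unity in t = log2(8 r): low + bands."""
    with np.errstate(divide="ignore"):
        t = np.log2(np.maximum(r, 1e-300) * 2.0 ** scales)
    low = np.zeros_like(r)
    low[t <= 0] = 1.0
    ramp = (t > 0) & (t < 1)
    low[ramp] = np.cos(np.pi / 2 * t[ramp]) ** 2
    parts = [low]
    for j in range(1, scales + 1):
        w = np.zeros_like(r)
        up = (t > j - 1) & (t <= j)
        w[up] = np.sin(np.pi / 2 * (t[up] - (j - 1))) ** 2
        if j < scales:
            down = (t > j) & (t < j + 1)
            w[down] = np.cos(np.pi / 2 * (t[down] - j)) ** 2
        else:
            w[t > j] = 1.0  # top band saturates to the Nyquist corner
        parts.append(w)
    return parts


def _shear_windows(u: np.ndarray, n_shears: int) -> list[np.ndarray]:
    """Squared angular windows on u in [0, n_shears - 1], saturating at the ends."""
    windows = []
    for k in range(n_shears):
        d = np.abs(u - k)
        w = np.where(d < 1.0, np.cos(np.pi / 2 * np.minimum(d, 1.0)) ** 2, 0.0)
        if k == 0:
            w = np.where(u <= 0, 1.0, w)
        if k == n_shears - 1:
            w = np.where(u >= n_shears - 1, 1.0, w)
        windows.append(w)
    return windows


def shearlet_system(
    size: int = 512, scales: int = N_SCALES, max_shear: int = MAX_SHEAR
) -> np.ndarray:
    """Frequency-domain shearlet filter bank (FFT layout).

    Returns an array of shape (1 + scales * 2 * (2 * max_shear + 1), size,
    size) whose squared magnitudes sum to 1 everywhere.
    """
    if size < 32 or size & (size - 1):
        raise ValueError("size must be a dyadic integer >= 32")
    f = np.fft.fftfreq(size)
    w1 = f[None, :]  # horizontal frequency
    w2 = f[:, None]  # vertical frequency
    r = 2.0 * np.maximum(np.abs(w1), np.abs(w2))  # max-norm radius, 1 at Nyquist

    radial = _radial_partition(r, scales)
    n_shears = 2 * max_shear + 1

    cone_h = np.abs(w1) >= np.abs(w2)
    cone_v = ~cone_h
    with np.errstate(divide="ignore", invalid="ignore"):
        slope_h = np.where(cone_h, np.divide(w2, np.where(w1 == 0, 1.0, w1)), 0.0)
        slope_v = np.where(cone_v, np.divide(w1, np.where(w2 == 0, 1.0, w2)), 0.0)

    filters = [np.sqrt(radial[0])]
    for j in range(1, scales + 1):
        for cone, slope in (("h", slope_h), ("v", slope_v)):
            u = (slope + 1.0) / 2.0 * (n_shears - 1)
            mask = cone_h if cone == "h" else cone_v
            for w_ang in _shear_windows(u, n_shears):
                filters.append(np.sqrt(radial[j] * w_ang * mask))
    return np.stack(filters)


@lru_cache(maxsize=2)
def _cached_system(size: int, scales: int, max_shear: int) -> np.ndarray:
    return shearlet_system(size, scales, max_shear)


class ShearletFeatures(BaseImageFeatureExtractor):
    """31-filter cone-adapted shearlet features (length 15872)."""

    method = "shelet"
    n_features = 15872

    def __init__(self, scales: int = N_SCALES, max_shear: int = MAX_SHEAR):
        self.scales = scales
        self.max_shear = max_shear

    def _extract(self, image: np.ndarray) -> np.ndarray:
        filters = _cached_system(image.shape[0], self.scales, self.max_shear)
        spectrum = np.fft.fft2(image)
        feats = []
        for filt in filters:
            coeff = np.fft.ifft2(spectrum * filt).real
            feats.append(block_average(np.abs(coeff), POOL_SHAPE).ravel())
        return np.concatenate(feats)


def shearlet_features(image) -> np.ndarray:
    """Length-15872 shearlet feature vector of a 512x512 image."""
    return ShearletFeatures().extract(image)
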