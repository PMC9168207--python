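"""Contourlet-style directional multi-resolution features.

Two-stage filter bank: a Laplacian pyramid splits the image into band-pass
residuals at dyadic scales, and each band-pass level is fed through a
directional filter bank that partitions the 2-D frequency plane into smooth
wedge pairs (a partition of unity, so the directional components sum back to
the band).  The default configuration (3 pyramid levels; 4, 4, 8 directions
fine -> coarse) yields 16 directional sub-bands, each block-averaged in
absolute value to 16x16: 4096 features.  The pyramid low-pass is excluded.
"""

from __future__ import annotations

import numpy as np
import pywt
from scipy import ndimage

from .base import BaseImageFeatureExtractor, Subband, SubbandSet, block_average

# orthonormal (db4) scaling filter: with adjoint expansion the pyramid is a
# tight frame, so analysis preserves energy and constants reproduce exactly
_KERNEL = np.asarray(pywt.Wavelet("db4").dec_lo)
POOL_SHAPE = (16, 16)
#: directions per band-pass level, fine -> coarse
DEFAULT_DIRECTIONS = (4, 4, 8)


def _reduce(x: np.ndarray) -> np.ndarray:
    for axis in (0, 1):
        x = ndimage.correlate1d(x, _KERNEL, axis=axis, mode="wrap")
    return x[::2, ::2]


def _expand(x: np.ndarray) -> np.ndarray:
    """Adjoint of :func:`_reduce`: zero-stuff, then convolve with the kernel."""
    up = np.zeros((x.shape[0] * 2, x.shape[1] * 2))
    up[::2, ::2] = x
    for axis in (0, 1):
        up = ndimage.convolve1d(up, _KERNEL, axis=axis, mode="wrap")
    return up


def laplacian_pyramid(image, levels: int = 3) -> SubbandSet:
    """Band-pass residual pyramid; collapse() reconstructs the input exactly.

    Sub-bands ordered coarse -> fine: low-pass first, then band-pass levels
    from coarsest to finest (full resolution last).
    """
    img = np.asarray(getattr(image, "pixels", image), dtype=float)
    if levels < 1 or min(img.shape) % (2**levels):
        raise ValueError("invalid number of pyramid levels for this image size")
    bands_fine_first = []
    cur = img
    for lev in range(levels):
        low = _reduce(cur)
        bands_fine_first.append(cur - _expand(low))
        cur = low
    subbands = [Subband(coeffs=cur, scale=0, orientation=0, tag="low")]
    for i, band in enumerate(reversed(bands_fine_first)):
        subbands.append(
            Subband(coeffs=band, scale=i + 1, orientation=0, tag=f"bp{levels - 1 - i}")
        )
    return SubbandSet(transform_name="laplacian_pyramid", subbands=subbands)


def collapse(pyramid: SubbandSet) -> np.ndarray:
    """Invert :func:`laplacian_pyramid`."""
    bands = pyramid.subbands
    cur = bands[0].coeffs
    for sub in bands[1:]:
        cur = sub.coeffs + _expand(cur)
    return cur


def _wedge_windows(shape: tuple[int, int], n_dirs: int) -> np.ndarray:
    """Smooth angular windows partitioning the frequency plane into wedge pairs.

    Raised-cosine (Meyer-type) windows in the angle-modulo-pi coordinate; the
    windows sum to exactly 1 at every frequency, so the directional components
    sum to the input.
    """
    fy = np.fft.fftfreq(shape[0])[:, None]
    fx = np.fft.fftfreq(shape[1])[None, :]
    theta = np.arctan2(fy, fx) % np.pi  # orientation axis, [0, pi)
    u = theta / np.pi * n_dirs
    windows = np.empty((n_dirs,) + shape)
    for j in range(n_dirs):
        d = np.abs((u - j + n_dirs / 2) % n_dirs - n_dirs / 2)
        w = np.where(d < 1.0, np.cos(np.pi / 2 * np.minimum(d, 1.0)) ** 2, 0.0)
        windows[j] = w
    # the origin has no orientation: split it evenly to keep the sum exact
    windows[:, 0, 0] = 1.0 / n_dirs
    return windows


def directional_filter_bank(band: np.ndarray, n_dirs: int) -> list[np.ndarray]:
    """Split a band into ``n_dirs`` directional components (sum = input)."""
    if n_dirs not in (2, 4, 8, 16):
        raise ValueError("n_dirs must be a power of two in {2, 4, 8, 16}")
    band = np.asarray(band, dtype=float)
    spectrum = np.fft.fft2(band)
    windows = _wedge_windows(band.shape, n_dirs)
    return [np.fft.ifft2(spectrum * w).real for w in windows]


class ContourletFeatures(BaseImageFeatureExtractor):
    """Laplacian pyramid + directional filter bank features (length 4096)."""

    method = "cntlet"
    n_features = 4096

    def __init__(self, levels: int = 3, directions: tuple[int, ...] = DEFAULT_DIRECTIONS):
        self.levels = levels
        self.directions = directions

    def _extract(self, image: np.ndarray) -> np.ndarray:
        pyr = laplacian_pyramid(image, levels=self.levels)
        # pyr.subbands: [low, coarsest bp, ..., finest bp]; directions are
        # specified fine -> coarse.
        bandpass = pyr.subbands[1:]
        dirs_coarse_first = list(reversed(self.directions))
        feats = []
        for sub, n_dirs in zip(bandpass, dirs_coarse_first):
            for comp in directional_filter_bank(sub.coeffs, n_dirs):
                feats.append(block_average(np.abs(comp), POOL_SHAPE).ravel())
        return np.concatenate(feats)


def contourlet_features(image) -> np.ndarray:
    """Length-4096 contourlet feature vector of a 512x512 image."""
    return ContourletFeatures().extract(image)
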