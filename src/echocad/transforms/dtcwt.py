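"""Dual-tree complex wavelet features.

Two parallel real wavelet trees whose filters are offset by (a quarter of) a
sample form an approximately analytic complex wavelet, giving six oriented
complex sub-bands per level (+/-15, +/-45, +/-75 degrees) with approximately
shift-invariant magnitudes — unlike the critically sampled DWT.

Filters: Farras nearly-symmetric orthonormal pair for the first stage and the
Kingsbury Q-shift 10-tap pair for deeper stages (tree B is the time reverse
of tree A).  Filtering is circular (periodic boundaries), so 512x512 inputs
give 256/128/64-sized level-1/2/3 sub-bands.

Features: 3 levels x 6 orientations, real and imaginary parts separately,
each block-averaged in absolute value to 16x16 -> 36 x 256 = 9216.
"""

from __future__ import annotations

import numpy as np

from .base import BaseImageFeatureExtractor, Subband, SubbandSet, block_average

POOL_SHAPE = (16, 16)

# Farras nearly-symmetric first-stage analysis filters (tree A): lo, hi
_FARRAS_LO = np.array(
    [0.0, -0.08838834764832, 0.08838834764832, 0.69587998903400,
     0.69587998903400, 0.08838834764832, -0.08838834764832,
     0.01122679215254, 0.01122679215254, 0.0]
)
_FARRAS_HI = np.array(
    [0.0, -0.01122679215254, 0.01122679215254, 0.08838834764832,
     0.08838834764832, -0.69587998903400, 0.69587998903400,
     -0.08838834764832, -0.08838834764832, 0.0]
)
# Kingsbury Q-shift 10-tap lowpass (tree A).  The published coefficients are
# rounded to 8 decimals; the even/odd tap sums are corrected below so the
# lowpass sums exactly to sqrt(2) and the derived highpass to exactly 0.
_QSHIFT_LO = np.array(
    [0.03516384, 0.0, -0.08832942, 0.23389032, 0.76027237,
     0.58751830, 0.0, -0.11430184, 0.0, 0.0]
)


def _balance(lo: np.ndarray) -> np.ndarray:
    lo = lo.copy()
    half = np.sqrt(2.0) / 2.0
    for parity in (0, 1):
        taps = np.flatnonzero(lo[parity::2] != 0) * 2 + parity
        lo[taps] += (half - lo[parity::2].sum()) / taps.size
    return lo


_QSHIFT_LO = _balance(_QSHIFT_LO)
# quadrature mirror: hi[n] = (-1)^n lo[N-1-n]
_QSHIFT_HI = _QSHIFT_LO[::-1] * np.where(np.arange(10) % 2, -1.0, 1.0)


def _tree_filters(level: int) -> dict:
    """(lo, hi) analysis filters per tree for the given level (1-based)."""
    if level == 1:
        lo_a, hi_a = _FARRAS_LO, _FARRAS_HI
        # tree B first-stage filters: one-sample-shifted reverses of tree A
        lo_b = np.roll(lo_a[::-1], -1)
        hi_b = np.roll(hi_a[::-1], -1)
    else:
        lo_a, hi_a = _QSHIFT_LO, _QSHIFT_HI
        lo_b, hi_b = _QSHIFT_LO[::-1], _QSHIFT_HI[::-1]
    return {"a": (lo_a, hi_a), "b": (lo_b, hi_b)}


def _filter_down(x: np.ndarray, filt: np.ndarray, axis: int) -> np.ndarray:
    """Circular convolution along ``axis`` followed by dyadic downsampling."""
    n = x.shape[axis]
    fpad = np.zeros(n)
    fpad[: filt.size] = filt
    shape = [1, 1]
    shape[axis] = n
    spec = np.fft.fft(x, axis=axis) * np.fft.fft(fpad).reshape(shape)
    y = np.fft.ifft(spec, axis=axis).real
    slicer = [slice(None), slice(None)]
    slicer[axis] = slice(0, n, 2)
    return y[tuple(slicer)]


def dtcwt_decompose(image, levels: int = 3) -> SubbandSet:
    """Complex oriented sub-bands of a dual-tree 2-D wavelet decomposition.

    Returns 6 complex sub-bands per level, ordered coarse -> fine, orientation
    index 0..5 within each level.
    """
    img = np.asarray(getattr(image, "pixels", image), dtype=float)
    if levels < 1 or min(img.shape) % (2**levels):
        raise ValueError("levels too deep for image size")

    # four branches: (row tree, col tree)
    lows = {(m, n): img for m in "ab" for n in "ab"}
    per_level: list[dict] = []
    for lev in range(1, levels + 1):
        filt = _tree_filters(lev)
        details: dict = {}
        new_lows = {}
        for (m, n), x in lows.items():
            lo_r, hi_r = filt[m]
            lo_c, hi_c = filt[n]
            lo_rows = _filter_down(x, lo_r, axis=0)
            hi_rows = _filter_down(x, hi_r, axis=0)
            new_lows[(m, n)] = _filter_down(lo_rows, lo_c, axis=1)
            details[("lh", m, n)] = _filter_down(lo_rows, hi_c, axis=1)
            details[("hl", m, n)] = _filter_down(hi_rows, lo_c, axis=1)
            details[("hh", m, n)] = _filter_down(hi_rows, hi_c, axis=1)
        per_level.append(details)
        lows = new_lows

    subbands = []
    for lev in range(levels, 0, -1):  # coarse -> fine
        details = per_level[lev - 1]
        orient = 0
        for kind in ("lh", "hl", "hh"):
            aa = details[(kind, "a", "a")]
            ab = details[(kind, "a", "b")]
            ba = details[(kind, "b", "a")]
            bb = details[(kind, "b", "b")]
            z_pos = ((aa - bb) + 1j * (ab + ba)) / np.sqrt(2.0)
            z_neg = ((aa + bb) + 1j * (ab - ba)) / np.sqrt(2.0)
            for z in (z_pos, z_neg):
                subbands.append(
                    Subband(
                        coeffs=z,
                        scale=levels - lev,
                        orientation=orient,
                        tag=f"{kind}{lev}{'+' if orient % 2 == 0 else '-'}",
                    )
                )
                orient += 1
    return SubbandSet(transform_name="dtcomwt", subbands=subbands)


class DTCWTFeatures(BaseImageFeatureExtractor):
    """Dual-tree complex wavelet features, real/imag pooled separately (9216)."""

    method = "dtcomwt"
    n_features = 9216

    def __init__(self, levels: int = 3):
        self.levels = levels

    def _extract(self, image: np.ndarray) -> np.ndarray:
        bands = dtcwt_decompose(image, levels=self.levels)
        feats = []
        for sub in bands:
            feats.append(block_average(np.abs(sub.coeffs.real), POOL_SHAPE).ravel())
            feats.append(block_average(np.abs(sub.coeffs.imag), POOL_SHAPE).ravel())
        return np.concatenate(feats)


def dtcwt_features(image) -> np.ndarray:
    """Length-9216 dual-tree complex wavelet feature vector."""
    return DTCWTFeatures().extract(image)


def magnitude_features(image, levels: int = 3) -> np.ndarray:
    """Block-averaged complex magnitudes (for shift-robustness analysis)."""
    bands = dtcwt_decompose(image, levels=levels)
    return np.concatenate(
        [block_average(np.abs(sub.coeffs), POOL_SHAPE).ravel() for sub in bands]
    )
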