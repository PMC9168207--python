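"""Empirical wavelet features with correntropy summarization.

The empirical wavelet transform adapts its filter bank to the signal: local
maxima of the Fourier magnitude spectrum define band boundaries (midpoints
between the largest peaks), and smooth Meyer-type band-pass filters
partitioning [0, pi] split the signal into modes that sum back to it exactly.

Each of the 512 image rows is decomposed into up to 4 modes; the feature is
the lag-1 correntropy of the highest-frequency mode: the mean Gaussian kernel
of successive-sample differences after z-scoring, V in (0, 1].  Rough bands
(large successive differences) give small V, smooth bands give V near 1:
512 features per image.
"""

from __future__ import annotations

import numpy as np

from .base import BaseImageFeatureExtractor

_CONST_TOL = 1e-12


def _detect_boundaries(spectrum: np.ndarray, max_modes: int) -> np.ndarray:
    """Boundaries (rad, in (0, pi)) as midpoints between the largest spectral peaks."""
    half = spectrum[: spectrum.size // 2 + 1]
    # strict local maxima of the magnitude spectrum on (0, pi)
    interior = np.arange(1, half.size - 1)
    is_peak = (half[interior] > half[interior - 1]) & (half[interior] >= half[interior + 1])
    peaks = interior[is_peak]
    if peaks.size == 0:
        return np.array([])
    order = np.argsort(half[peaks])[::-1]
    top = np.sort(peaks[order[:max_modes]])
    mids = (top[:-1] + top[1:]) / 2.0
    n = spectrum.size
    return mids * 2.0 * np.pi / n


def _meyer_steps(n: int, boundaries: np.ndarray) -> list[np.ndarray]:
    """Smooth decreasing steps S_b(|w|) (1 -> 0 across each boundary).

    Transition half-width is a fraction of the gap to the neighbouring
    boundaries so the steps never overlap and the filters stay non-negative.
    """
    w = np.abs(2 * np.pi * np.fft.fftfreq(n))
    edges = np.concatenate([[0.0], boundaries, [np.pi]])
    steps = []
    for i, b in enumerate(boundaries):
        gap = min(b - edges[i], edges[i + 2] - b)
        gamma = 0.5 * gap
        s = np.ones(n)
        trans = (w > b - gamma) & (w < b + gamma)
        s[w >= b + gamma] = 0.0
        s[trans] = np.cos(np.pi / 4 * ((w[trans] - (b - gamma)) / gamma)) ** 2
        steps.append(s)
    return steps


def ewt_decompose_1d(
    signal: np.ndarray, max_modes: int = 4
) -> tuple[list[np.ndarray], np.ndarray]:
    """Empirical wavelet modes of a 1-D signal; modes sum to the signal.

    Returns (modes, boundaries).  A constant signal yields one trivial mode.
    """
    signal = np.asarray(signal, dtype=float)
    if not np.all(np.isfinite(signal)):
        raise ValueError("signal must be finite")
    if max_modes < 2:
        raise ValueError("max_modes must be >= 2")
    if np.ptp(signal) < _CONST_TOL:
        return [signal.copy()], np.array([])

    spec = np.fft.fft(signal)
    boundaries = _detect_boundaries(np.abs(spec), max_modes)
    if boundaries.size == 0:
        return [signal.copy()], boundaries

    steps = _meyer_steps(signal.size, boundaries)
    # filters as differences of nested smooth steps: an exact partition of unity
    prev = np.ones(signal.size)
    modes = []
    for s in steps:
        modes.append(np.fft.ifft(spec * (prev - s)).real)
        prev = s
    modes.append(np.fft.ifft(spec * prev).real)
    modes = modes[::-1]  # low frequency first
    return modes, boundaries


def correntropy_lag1(signal: np.ndarray, sigma: float = 1.0) -> float:
    """Mean Gaussian kernel of successive differences of the z-scored signal.

    V = (1/(N-1)) sum exp(-(x[i+1]-x[i])^2 / (2 sigma^2)), in (0, 1].
    Constant signals return exactly 1.0.
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    x = np.asarray(signal, dtype=float)
    if x.size < 2:
        raise ValueError("signal must have length >= 2")
    sd = x.std()
    if sd < _CONST_TOL:
        return 1.0
    z = (x - x.mean()) / sd
    d = np.diff(z)
    return float(np.exp(-(d**2) / (2.0 * sigma**2)).mean())


class EWTFeatures(BaseImageFeatureExtractor):
    """Row-wise EWT; lag-1 correntropy of the highest-frequency mode (length 512)."""

    method = "ewt"
    n_features = 512

    def __init__(self, max_modes: int = 4, sigma: float = 1.0):
        self.max_modes = max_modes
        self.sigma = sigma

    def _extract(self, image: np.ndarray) -> np.ndarray:
        out = np.empty(image.shape[0])
        for i, row in enumerate(image):
            modes, _ = ewt_decompose_1d(row, max_modes=self.max_modes)
            out[i] = correntropy_lag1(modes[-1], sigma=self.sigma)
        return out


def ewt_features(image) -> np.ndarray:
    """Length-512 empirical-wavelet correntropy feature vector."""
    return EWTFeatures().extract(image)
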