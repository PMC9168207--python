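"""Shared plumbing for the multi-resolution feature extractors.

Every extractor maps a 512x512 image to a fixed-length feature vector by
decomposing it into sub-bands and block-averaging coefficient magnitudes to a
small fixed grid.  Extractors are scikit-learn transformers: stateless,
``fit`` is a no-op, ``transform`` maps a stack of images to a feature matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from ..preprocess import STANDARD_SIZE, EchoImage


def block_average(matrix: np.ndarray, out_shape: tuple[int, int]) -> np.ndarray:
    """Downsample by averaging non-overlapping blocks; shapes must divide."""
    matrix = np.asarray(matrix, dtype=float)
    r, c = out_shape
    h, w = matrix.shape
    if h % r or w % c:
        raise ValueError(f"shape {matrix.shape} not divisible into {out_shape} blocks")
    return matrix.reshape(r, h // r, c, w // c).mean(axis=(1, 3))


@dataclass
class Subband:
    """One coefficient matrix of a decomposition, indexed by scale/orientation."""

    coeffs: np.ndarray
    scale: int
    orientation: int
    tag: str


@dataclass
class SubbandSet:
    """Ordered (coarse -> fine, orientation ascending) collection of sub-bands."""

    transform_name: str
    subbands: list[Subband] = field(default_factory=list)
    source_id: str = ""

    def __iter__(self):
        return iter(self.subbands)

    def __len__(self) -> int:
        return len(self.subbands)


def as_image_array(x) -> np.ndarray:
    """Coerce an EchoImage / 2-D array to a float 512x512 array."""
    if isinstance(x, EchoImage):
        x = x.pixels
    x = np.asarray(x, dtype=float)
    if x.shape != (STANDARD_SIZE, STANDARD_SIZE):
        raise ValueError(f"expected a {STANDARD_SIZE}x{STANDARD_SIZE} image, got {x.shape}")
    return x


def as_image_stack(X) -> np.ndarray:
    """Coerce a list of EchoImages / a 3-D array / one image to (n, 512, 512)."""
    if isinstance(X, EchoImage):
        return as_image_array(X)[None]
    X = np.asarray(
        [as_image_array(x) for x in X] if isinstance(X, (list, tuple)) else X,
        dtype=float,
    )
    if X.ndim == 2:
        X = X[None]
    if X.ndim != 3 or X.shape[1:] != (STANDARD_SIZE, STANDARD_SIZE):
        raise ValueError("expected images of shape (n, 512, 512)")
    return X


class BaseImageFeatureExtractor(TransformerMixin, BaseEstimator):
    """Stateless image -> fixed-length feature vector transformer."""

    #: registry name, e.g. "dwt"
    method: str = ""
    #: contracted output length
    n_features: int = 0

    def fit(self, X, y=None):
        return self

    def transform(self, X) -> np.ndarray:
        stack = as_image_stack(X)
        out = np.empty((stack.shape[0], self.n_features))
        for i, img in enumerate(stack):
            out[i] = self.extract(img)
        return out

    def extract(self, image) -> np.ndarray:
        """Feature vector for a single image."""
        vec = self._extract(as_image_array(image))
        if vec.shape != (self.n_features,):
            raise AssertionError(
                f"{self.method}: produced {vec.shape[0]} features, "
                f"contract is {self.n_features}"
            )
        if not np.all(np.isfinite(vec)):
            raise AssertionError(f"{self.method}: non-finite features")
        return vec

    def _extract(self, image: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError
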