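"""Multi-resolution feature extractors: 512x512 image -> fixed-length vector.

Six methods with hard length contracts:

======== ====== ==========================================
method   length decomposition
======== ====== ==========================================
dwt        2560 3-level db4 DWT (10 sub-bands)
cntlet     4096 Laplacian pyramid + directional filter bank
dtcomwt    9216 3-level dual-tree complex wavelet
shelet    15872 31-filter cone-adapted shearlet system
cwt        8192 Mexican-hat wavelet, 8 dyadic scales
ewt         512 row-wise empirical wavelet + correntropy
======== ====== ==========================================

The curvelet slot ("crvlet") exists in the registry but is not implemented.
"""

from __future__ import annotations

from .base import BaseImageFeatureExtractor, Subband, SubbandSet, block_average
from .dwt import DWTFeatures, dwt_decompose, dwt_features
from .contourlet import (
    ContourletFeatures,
    collapse,
    contourlet_features,
    directional_filter_bank,
    laplacian_pyramid,
)
from .dtcwt import DTCWTFeatures, dtcwt_decompose, dtcwt_features
from .shearlet import ShearletFeatures, shearlet_features, shearlet_system
from .cwt import CWT2DFeatures, cwt2d_features
from .ewt import EWTFeatures, correntropy_lag1, ewt_decompose_1d, ewt_features

_EXTRACTORS = {
    "dwt": DWTFeatures,
    "cntlet": ContourletFeatures,
    "dtcomwt": DTCWTFeatures,
    "shelet": ShearletFeatures,
    "cwt": CWT2DFeatures,
    "ewt": EWTFeatures,
}

#: contracted feature-vector length per method
FEATURE_LENGTHS = {name: cls.n_features for name, cls in _EXTRACTORS.items()}

METHODS = tuple(_EXTRACTORS)


def get_extractor(method: str, **params) -> BaseImageFeatureExtractor:
    """Instantiate a feature extractor by registry name."""
    if method == "crvlet":
        raise NotImplementedError("the curvelet transform is not implemented")
    if method not in _EXTRACTORS:
        raise KeyError(f"unknown transform method {method!r}; choose from {METHODS}")
    return _EXTRACTORS[method](**params)


__all__ = [
    "BaseImageFeatureExtractor",
    "Subband",
    "SubbandSet",
    "block_average",
    "DWTFeatures",
    "dwt_decompose",
    "dwt_features",
    "ContourletFeatures",
    "collapse",
    "contourlet_features",
    "directional_filter_bank",
    "laplacian_pyramid",
    "DTCWTFeatures",
    "dtcwt_decompose",
    "dtcwt_features",
    "ShearletFeatures",
    "shearlet_features",
    "shearlet_system",
    "CWT2DFeatures",
    "cwt2d_features",
    "EWTFeatures",
    "correntropy_lag1",
    "ewt_decompose_1d",
    "ewt_features",
    "FEATURE_LENGTHS",
    "METHODS",
    "get_extractor",
]
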