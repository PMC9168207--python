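"""Preprocessing of raw ultrasound frames.

Raw echocardiogram stills carry burned-in annotations (patient text, depth
markers, ECG trace) outside the imaging sector.  This module removes them by
masking, enhances contrast with CLAHE, and standardizes every frame to a
512x512 grayscale image in [0, 1]:

    build_annotation_mask -> remove_annotations -> apply_clahe -> standardize

The composite is deterministic: the same input always yields a bit-identical
output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage import exposure, measure, transform

#: side length of the standardized image
STANDARD_SIZE = 512

#: intensity threshold (fraction of frame max) for annotation candidates
BRIGHT_FRACTION = 0.9
#: connected components smaller than this are annotation candidates
SMALL_AREA = 2000
#: width of the border band (fraction of frame size) that annotations touch
BORDER_BAND = 0.05
#: foreground threshold after median filtering, used to find the sector
FOREGROUND_LEVEL = 0.02

VALID_LABELS = ("normal", "htn", "unknown")


@dataclass
class RawFrame:
    """A raw grayscale ultrasound frame with provenance.

    pixels are float in [0, 1], at least 64x64.
    """

    pixels: np.ndarray
    source_id: str = ""
    label: str = "unknown"

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2:
            raise ValueError("RawFrame pixels must be a 2-D matrix")
        if self.pixels.shape[0] < 64 or self.pixels.shape[1] < 64:
            raise ValueError("RawFrame must be at least 64x64")
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("RawFrame pixels must be finite")
        if self.pixels.min() < 0 or self.pixels.max() > 1:
            raise ValueError("RawFrame pixels must lie in [0, 1]")
        if self.label not in VALID_LABELS:
            raise ValueError(f"label must be one of {VALID_LABELS}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass
class AnnotationMask:
    """Binary mask over a frame; 1 marks annotation/overlay pixels to remove."""

    mask: np.ndarray

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask).astype(bool)
        if self.mask.ndim != 2:
            raise ValueError("mask must be 2-D")

    @property
    def fraction(self) -> float:
        return float(self.mask.mean())


@dataclass
class EchoImage:
    """Standardized 512x512 frame ready for feature extraction."""

    pixels: np.ndarray
    label: str = "unknown"
    preprocessing_log: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.shape != (STANDARD_SIZE, STANDARD_SIZE):
            raise ValueError(f"EchoImage must be {STANDARD_SIZE}x{STANDARD_SIZE}")
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("EchoImage pixels must be finite")
        if self.pixels.min() < -1e-12 or self.pixels.max() > 1 + 1e-12:
            raise ValueError("EchoImage pixels must lie in [0, 1]")
        self.pixels = np.clip(self.pixels, 0.0, 1.0)


def _largest_foreground(pixels: np.ndarray) -> np.ndarray:
    """Largest connected component of the median-filtered foreground, holes filled.

    This is the imaging sector for any frame whose sector is the dominant
    bright structure.
    """
    med = ndimage.median_filter(pixels, size=5)
    fg = med > FOREGROUND_LEVEL
    if not fg.any():
        raise ValueError("empty frame")
    labels = measure.label(fg, connectivity=2)
    counts = np.bincount(labels.ravel())
    counts[0] = 0
    sector = labels == counts.argmax()
    sector = ndimage.binary_fill_holes(sector)
    # the median filter erodes ~2 px at the sector boundary; dilate back so
    # true sector-edge pixels are never flagged as background
    return ndimage.binary_dilation(sector, iterations=2)


def build_annotation_mask(frame: RawFrame) -> AnnotationMask:
    """Flag burned-in annotations and everything outside the imaging sector.

    The rule: pixels outside the largest connected foreground (the sector)
    are flagged, as are high-intensity connected components that are small
    (< 2000 px) or touch the outer 5% border band.  The sector interior is
    never flagged.
    """
    pixels = frame.pixels
    if not pixels.any():
        raise ValueError("empty frame")
    sector = _largest_foreground(pixels)

    bright = pixels >= BRIGHT_FRACTION * pixels.max()
    labels = measure.label(bright, connectivity=2)
    h, w = pixels.shape
    bh = max(1, int(round(BORDER_BAND * h)))
    bw = max(1, int(round(BORDER_BAND * w)))
    border = np.zeros_like(bright)
    border[:bh, :] = border[-bh:, :] = True
    border[:, :bw] = border[:, -bw:] = True

    candidates = np.zeros_like(bright)
    for region in measure.regionprops(labels):
        comp = labels == region.label
        if region.area < SMALL_AREA or (comp & border).any():
            candidates |= comp

    mask = ~sector | (candidates & ~sector)
    return AnnotationMask(mask=mask)


def remove_annotations(
    frame: RawFrame, mask: AnnotationMask
) -> tuple[RawFrame, tuple[int, int, int, int]]:
    """Zero out flagged pixels; return the cleaned frame and a crop box.

    The bounding box (r0, r1, c0, c1), slice semantics, tightly encloses the
    unflagged foreground (the sector) and is used by :func:`standardize`.
    """
    if mask.mask.shape != frame.pixels.shape:
        raise ValueError("mask shape does not match frame shape")
    cleaned = frame.pixels * ~mask.mask
    if cleaned.any():
        fg = _largest_foreground(cleaned)
    else:
        fg = ~mask.mask
    rows = np.flatnonzero(fg.any(axis=1))
    cols = np.flatnonzero(fg.any(axis=0))
    if rows.size == 0 or cols.size == 0:
        bbox = (0, frame.pixels.shape[0], 0, frame.pixels.shape[1])
    else:
        bbox = (int(rows[0]), int(rows[-1]) + 1, int(cols[0]), int(cols[-1]) + 1)
    out = RawFrame(pixels=cleaned, source_id=frame.source_id, label=frame.label)
    return out, bbox


def apply_clahe(
    image: np.ndarray,
    clip_limit: float = 0.01,
    tiles: tuple[int, int] = (8, 8),
    nbins: int = 256,
) -> np.ndarray:
    """Contrast-limited adaptive histogram equalization.

    Tile-wise histogram equalization with clipping and bilinear interpolation
    between tile mappings, via scikit-image.  ``clip_limit`` is the clipping
    fraction in (0, 1]; ``tiles`` the (rows, cols) tile grid.
    """
    image = np.asarray(image, dtype=float)
    if not np.all(np.isfinite(image)):
        raise ValueError("non-finite pixels")
    if image.min() < 0 or image.max() > 1:
        raise ValueError("image must lie in [0, 1]")
    if not 0 < clip_limit <= 1:
        raise ValueError("clip_limit must be in (0, 1]")
    if tiles[0] < 1 or tiles[1] < 1:
        raise ValueError("tiles must be at least (1, 1)")
    if image.max() - image.min() < 1e-12:
        # degenerate histogram: equalization maps a constant to a constant
        return image.copy()
    kernel = (
        int(np.ceil(image.shape[0] / tiles[0])),
        int(np.ceil(image.shape[1] / tiles[1])),
    )
    out = exposure.equalize_adapthist(
        image, kernel_size=kernel, clip_limit=clip_limit, nbins=nbins
    )
    return np.clip(out, 0.0, 1.0)


def standardize(frame: RawFrame, bbox: tuple[int, int, int, int]) -> EchoImage:
    """Crop to ``bbox`` and resample to 512x512 with bilinear interpolation."""
    r0, r1, c0, c1 = bbox
    h, w = frame.pixels.shape
    if not (0 <= r0 < r1 <= h and 0 <= c0 < c1 <= w):
        raise ValueError("bbox outside frame or degenerate")
    crop = frame.pixels[r0:r1, c0:c1]
    if crop.shape == (STANDARD_SIZE, STANDARD_SIZE):
        pixels = crop.copy()
    else:
        pixels = transform.resize(
            crop,
            (STANDARD_SIZE, STANDARD_SIZE),
            order=1,
            mode="edge",
            anti_aliasing=False,
            preserve_range=True,
        )
    return EchoImage(
        pixels=np.clip(pixels, 0.0, 1.0),
        label=frame.label,
        preprocessing_log=[f"crop{bbox}", f"resize{(STANDARD_SIZE, STANDARD_SIZE)}"],
    )


def preprocess_frame(
    frame: RawFrame,
    clip_limit: float = 0.01,
    tiles: tuple[int, int] = (8, 8),
) -> EchoImage:
    """Full preprocessing chain: mask -> remove -> CLAHE -> crop/resize."""
    mask = build_annotation_mask(frame)
    cleaned, bbox = remove_annotations(frame, mask)
    enhanced = apply_clahe(cleaned.pixels, clip_limit=clip_limit, tiles=tiles)
    echo = standardize(
        RawFrame(pixels=enhanced, source_id=frame.source_id, label=frame.label), bbox
    )
    echo.preprocessing_log = [
        "annotation_mask",
        f"clahe(clip={clip_limit},tiles={tiles})",
    ] + echo.preprocessing_log
    return echo
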