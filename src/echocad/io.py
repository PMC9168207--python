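"""Readers and writers for images, feature matrices and reports."""

from __future__ import annotations

import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .preprocess import EchoImage, RawFrame

_LUMA = np.array([0.299, 0.587, 0.114])


def _to_gray01(arr: np.ndarray) -> np.ndarray:
    arr = np.asarray(arr)
    if arr.ndim == 3:
        arr = arr[..., :3] @ _LUMA
    arr = arr.astype(float)
    if np.issubdtype(np.asarray(arr).dtype, np.floating) and arr.max() <= 1.0:
        scale = 1.0
    elif arr.max() <= 255:
        scale = 255.0
    else:
        scale = 65535.0
    return np.clip(arr / scale, 0.0, 1.0)


def load_frame(path: str | Path, label: str = "unknown") -> RawFrame:
    """Load a PNG/TIFF (or single-frame DICOM) image as a grayscale RawFrame."""
    path = Path(path)
    if path.suffix.lower() in (".dcm", ".dicom"):
        import pydicom

        ds = pydicom.dcmread(path)
        arr = ds.pixel_array.astype(float)
        arr = (arr - arr.min()) / max(arr.max() - arr.min(), 1e-12)
    else:
        arr = _to_gray01(iio.imread(path))
    return RawFrame(pixels=arr, source_id=path.name, label=label)


def save_echo_image(echo: EchoImage, path: str | Path) -> None:
    """Write a standardized image as 16-bit PNG plus a JSON log sidecar."""
    path = Path(path)
    iio.imwrite(path, np.round(echo.pixels * 65535).astype(np.uint16))
    sidecar = {"label": echo.label, "preprocessing_log": echo.preprocessing_log}
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def load_echo_image(path: str | Path) -> EchoImage:
    path = Path(path)
    pixels = np.asarray(iio.imread(path), dtype=float) / 65535.0
    label, log = "unknown", []
    sidecar = path.with_suffix(".json")
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        label = meta.get("label", "unknown")
        log = meta.get("preprocessing_log", [])
    return EchoImage(pixels=pixels, label=label, preprocessing_log=log)


def write_feature_csv(
    X: np.ndarray, labels, method: str, path: str | Path
) -> pd.DataFrame:
    """Feature matrix as CSV: one row per image, '<method>_f<idx>' columns, label last."""
    X = np.asarray(X, dtype=float)
    df = pd.DataFrame(X, columns=[f"{method}_f{j}" for j in range(X.shape[1])])
    df["label"] = list(labels)
    df.to_csv(path, index=False)
    return df


def read_feature_csv(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    """Inverse of :func:`write_feature_csv`: (features, labels)."""
    df = pd.read_csv(path)
    labels = df.pop("label").to_numpy()
    return df.to_numpy(dtype=float), labels


def write_feature_container(
    X: np.ndarray, labels, method: str, path: str | Path, config: dict | None = None
) -> None:
    """Compressed binary feature container plus a JSON manifest sidecar."""
    path = Path(path)
    np.savez_compressed(path.with_suffix(".npz"), features=np.asarray(X, dtype=float),
                        labels=np.asarray(labels, dtype=str))
    manifest = {"method": method, "n_samples": int(len(labels)),
                "n_features": int(np.asarray(X).shape[1]), "config": config or {}}
    path.with_suffix(".json").write_text(json.dumps(manifest, indent=2))


def read_feature_container(path: str | Path) -> tuple[np.ndarray, np.ndarray, dict]:
    """Inverse of :func:`write_feature_container`: (features, labels, manifest)."""
    path = Path(path)
    data = np.load(path.with_suffix(".npz"))
    manifest = json.loads(path.with_suffix(".json").read_text())
    return data["features"], data["labels"], manifest


def write_manifest(records: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(records, indent=2, default=str))
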