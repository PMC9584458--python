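"""Image and config I/O helpers (PNG/BMP/TIFF via imageio, JSON configs)."""

from __future__ import annotations

import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np

from .cgh import PhaseHologram, dequantize_phase

__all__ = [
    "read_image",
    "read_gray",
    "write_gray_u8",
    "write_mask",
    "write_hologram",
    "read_hologram",
    "write_json",
    "read_json",
]


def read_image(path: str | Path) -> np.ndarray:
    """Read an image as float in [0, 1] (RGB kept, alpha dropped)."""
    try:
        arr = iio.imread(path)
    except Exception as exc:  # noqa: BLE001 - surface the file name
        raise IOError(f"cannot read image file {path!s}: {exc}") from exc
    arr = np.asarray(arr)
    if arr.ndim == 3 and arr.shape[2] == 4:
        arr = arr[:, :, :3]
    if np.issubdtype(arr.dtype, np.integer):
        arr = arr.astype(float) / np.iinfo(arr.dtype).max
    else:
        arr = arr.astype(float)
    return arr


def read_gray(path: str | Path) -> np.ndarray:
    arr = read_image(path)
    if arr.ndim == 3:
        arr = arr.mean(axis=2)
    return arr


def write_gray_u8(path: str | Path, image: np.ndarray) -> None:
    """Write a float image scaled to 8 bits (max maps to 255)."""
    img = np.asarray(image, dtype=float)
    peak = img.max()
    if peak > 0:
        img = img / peak
    iio.imwrite(Path(path), (np.clip(img, 0, 1) * 255).round().astype(np.uint8))


def write_mask(path: str | Path, mask: np.ndarray) -> None:
    iio.imwrite(Path(path), (np.asarray(mask, bool).astype(np.uint8) * 255))


def write_hologram(path: str | Path, hologram: PhaseHologram) -> None:
    """Save a phase hologram as SLM-ready 8-bit grayscale (0..255 = [0, 2pi))."""
    iio.imwrite(Path(path), hologram.quantized_u8)


def read_hologram(path: str | Path) -> PhaseHologram:
    arr = iio.imread(path)
    if arr.ndim == 3:
        arr = arr[:, :, 0]
    return PhaseHologram(dequantize_phase(arr))


def write_json(path: str | Path, payload: dict) -> None:
    Path(path).write_text(json.dumps(payload, indent=2, default=_json_default))


def read_json(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())


def _json_default(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    raise TypeError(f"not JSON serializable: {type(obj)}")
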