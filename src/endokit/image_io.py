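"""Reading and writing images, masks and float sidecars."""

from __future__ import annotations

from pathlib import Path

import imageio.v3 as iio
import numpy as np

from .errors import ImageFormatError

__all__ = [
    "read_rgb",
    "write_enhanced",
    "read_mask",
    "write_mask",
]


def read_rgb(path: str | Path) -> np.ndarray:
    """Read an 8-bit RGB PNG/JPEG; alpha channels are dropped."""
    arr = iio.imread(path)
    if arr.ndim == 2:
        raise ImageFormatError(f"{path}: expected RGB, got a single channel")
    if arr.shape[2] == 4:
        arr = arr[:, :, :3]
    if arr.shape[2] != 3:
        raise ImageFormatError(f"{path}: expected 3 channels, got {arr.shape[2]}")
    return np.asarray(arr, dtype=np.uint8)


def write_enhanced(path: str | Path, pixels: np.ndarray, sidecar: bool = True) -> None:
    """Write a real-valued image as a clipped/rounded 8-bit PNG.

    With ``sidecar`` the exact float array is also saved next to the PNG as
    a .npy file so downstream steps can avoid quantization loss.
    """
    path = Path(path)
    quantized = np.clip(np.rint(pixels), 0, 255).astype(np.uint8)
    iio.imwrite(path, quantized)
    if sidecar:
        np.save(path.with_suffix(".npy"), np.asarray(pixels, dtype=np.float64))


def read_mask(path: str | Path) -> np.ndarray:
    """Read a single-channel 0/255 PNG as a boolean mask."""
    arr = iio.imread(path)
    if arr.ndim == 3:
        arr = arr[..., 0]
    return arr > 127


def write_mask(path: str | Path, mask: np.ndarray) -> None:
    iio.imwrite(Path(path), (np.asarray(mask, bool) * np.uint8(255)))
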