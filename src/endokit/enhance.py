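"""Endoscopy frame enhancement.

The chain is deliberately simple and classical: convert the RGB frame to
grayscale by averaging the three channels, smooth it with a square averaging
filter that excludes the central pixel, take a discrete Laplacian, and
subtract the Laplacian response from the smoothed image.  Smoothing removes
specular/debris artifacts while the Laplacian subtraction sharpens lesion
edges (unsharp-masking style).

All arithmetic is carried out in float64; quantization to 8-bit happens only
when an image is exported to PNG (see :mod:`endokit.image_io`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .errors import ImageFormatError, ParameterError

#: 4-connected discrete Laplacian stencil (default).
LAPLACIAN_4 = np.array([[0.0, 1.0, 0.0], [1.0, -4.0, 1.0], [0.0, 1.0, 0.0]])
#: 8-connected alternative.
LAPLACIAN_8 = np.array([[1.0, 1.0, 1.0], [1.0, -8.0, 1.0], [1.0, 1.0, 1.0]])

_KERNELS = {4: LAPLACIAN_4, 8: LAPLACIAN_8}


@dataclass
class EnhancedImage:
    """Real-valued enhanced frame plus the parameters that produced it."""

    pixels: np.ndarray
    window: int = 5
    kernel: int = 4
    include_center: bool = False

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


def validate_rgb(image: np.ndarray) -> np.ndarray:
    """Check the RGB image contract: H×W×3, 8-bit range, at least 16×16."""
    arr = np.asarray(image)
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise ImageFormatError(
            f"expected an H×W×3 RGB raster, got shape {arr.shape}"
        )
    if arr.shape[0] < 16 or arr.shape[1] < 16:
        raise ImageFormatError(
            f"image must be at least 16×16 pixels, got {arr.shape[:2]}"
        )
    if arr.min() < 0 or arr.max() > 255:
        raise ImageFormatError("RGB intensities must lie in [0, 255]")
    return arr


def to_gray(image: np.ndarray) -> np.ndarray:
    """Unweighted per-pixel mean of the three color channels.

    Luminance weighting is intentionally not used; the grayscale plane is
    the plain arithmetic mean of R, G and B.
    """
    arr = validate_rgb(image)
    return arr.astype(np.float64).mean(axis=2)


def average_filter(
    gray: np.ndarray, window: int = 5, include_center: bool = False
) -> np.ndarray:
    """Square-window averaging filter with the center pixel excluded.

    Each pixel is replaced by the mean of the ``window² − 1`` surrounding
    pixels in its window (24 neighbors for the default 5×5 window).  Borders
    are handled by edge replication.  ``include_center=True`` switches to the
    conventional inclusive box mean for comparison.
    """
    if window < 3 or window % 2 == 0:
        raise ParameterError(f"window must be odd and ≥ 3, got {window}")
    arr = np.asarray(gray, dtype=np.float64)
    if arr.ndim != 2:
        raise ImageFormatError(f"expected a 2-D gray image, got shape {arr.shape}")
    kernel = np.ones((window, window))
    if include_center:
        kernel /= window * window
    else:
        kernel[window // 2, window // 2] = 0.0
        kernel /= window * window - 1
    return ndimage.correlate(arr, kernel, mode="nearest")


def laplacian_filter(gray: np.ndarray, kernel: int = 4) -> np.ndarray:
    """Discrete Laplacian with the 4- or 8-connected stencil, replicate borders."""
    arr = np.asarray(gray, dtype=np.float64)
    if arr.ndim != 2:
        raise ImageFormatError(f"expected a 2-D gray image, got shape {arr.shape}")
    try:
        stencil = _KERNELS[kernel]
    except KeyError:
        raise ParameterError(f"kernel must be 4 or 8, got {kernel}") from None
    return ndimage.correlate(arr, stencil, mode="nearest")


def enhance(
    image: np.ndarray,
    window: int = 5,
    kernel: int = 4,
    include_center: bool = False,
) -> EnhancedImage:
    """Full enhancement: smoothed grayscale minus Laplacian response.

    Returns the average-filtered gray plane minus the Laplacian-filtered
    gray plane, element-wise, as real values (no clipping).
    """
    gray = to_gray(image)
    smoothed = average_filter(gray, window=window, include_center=include_center)
    edges = laplacian_filter(gray, kernel=kernel)
    return EnhancedImage(
        pixels=smoothed - edges,
        window=window,
        kernel=kernel,
        include_center=include_center,
    )
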