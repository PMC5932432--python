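"""Reading and writing of grayscale images, masks and float responses.

Images (PNG/PGM/TIFF, 8- or 16-bit integer or float) are converted to float64
in [0, 1] on read.  Detection responses are written as a 16-bit PNG preview
plus a float32 ``.npy`` sidecar so thresholding never loses precision to
quantization; masks are 8-bit {0, 255} PNG.
"""

from __future__ import annotations

from pathlib import Path

import imageio.v3 as iio
import numpy as np

__all__ = [
    "read_image",
    "write_image",
    "read_mask",
    "write_mask",
    "write_response",
    "read_response",
]


def read_image(path) -> np.ndarray:
    """Load a grayscale image as float64 in [0, 1] (integer types rescaled by dtype max)."""
    arr = iio.imread(Path(path))
    if arr.ndim == 3:  # collapse RGB(A) to luminance-agnostic mean
        arr = arr[..., :3].mean(axis=-1)
    if np.issubdtype(arr.dtype, np.integer):
        return arr.astype(np.float64) / np.iinfo(arr.dtype).max
    return arr.astype(np.float64)


def write_image(path, image: np.ndarray) -> None:
    """Write a float image in [0, 1] as 16-bit PNG."""
    image = np.asarray(image, dtype=np.float64)
    if image.min() < 0 or image.max() > 1:
        raise ValueError("image must be within [0, 1]; clip before writing")
    iio.imwrite(Path(path), np.round(image * 65535).astype(np.uint16))


def read_mask(path) -> np.ndarray:
    arr = iio.imread(Path(path))
    if arr.ndim == 3:
        arr = arr[..., 0]
    return arr > (np.iinfo(arr.dtype).max // 2 if np.issubdtype(arr.dtype, np.integer) else 0.5)


def write_mask(path, mask: np.ndarray) -> None:
    iio.imwrite(Path(path), np.where(np.asarray(mask, bool), 255, 0).astype(np.uint8))


def write_response(path_stem, response: np.ndarray) -> None:
    """16-bit PNG preview (min-max scaled) plus lossless float32 .npy sidecar."""
    path_stem = Path(path_stem)
    response = np.asarray(response, dtype=np.float64)
    np.save(path_stem.with_suffix(".npy"), response.astype(np.float32))
    lo, hi = response.min(), response.max()
    preview = (response - lo) / (hi - lo) if hi > lo else np.zeros_like(response)
    iio.imwrite(path_stem.with_suffix(".png"), np.round(preview * 65535).astype(np.uint16))


def read_response(path_stem) -> np.ndarray:
    return np.load(Path(path_stem).with_suffix(".npy")).astype(np.float64)
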