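"""Reading and writing greyscale images.

Lossless single-channel formats only: PNG, TIFF, PGM, at 8 or 16 bits.
Pixels are promoted to float64 on read (the display range is inferred from
the stored bit depth) and quantized — round half away from zero, clip to the
display range — only on write.
"""

from __future__ import annotations

import os

import imageio.v3 as iio
import numpy as np

from .morphology import GreyImage

__all__ = ["read_image", "write_image", "quantize"]

_SUPPORTED = {".png", ".tif", ".tiff", ".pgm"}
_LOSSY = {".jpg", ".jpeg", ".webp"}


def read_image(path: str, collapse_channels: bool = False) -> GreyImage:
    """Read a PNG/TIFF/PGM file as a GreyImage.

    Multi-channel files are rejected unless ``collapse_channels`` is set,
    in which case channels are averaged.  The display range follows the
    stored dtype: [0, 255] for 8-bit, [0, 65535] for 16-bit.
    """
    ext = os.path.splitext(path)[1].lower()
    if ext not in _SUPPORTED:
        raise ValueError(
            f"unsupported format {ext!r}; supported formats are PNG, TIFF and PGM"
        )
    arr = iio.imread(path)
    if arr.ndim == 3:
        if not collapse_channels:
            raise ValueError(
                f"{path} has {arr.shape[-1]} channels; pass collapse_channels=True "
                "to average them into one"
            )
        arr = arr.astype(np.float64).mean(axis=-1)
    if arr.ndim != 2:
        raise ValueError(f"{path} is not a 2-D image (shape {arr.shape})")
    if arr.dtype == np.uint8:
        hi = 255.0
    elif arr.dtype == np.uint16:
        hi = 65535.0
    elif np.issubdtype(arr.dtype, np.floating):
        # collapsed RGB lands here; infer 8-bit unless values exceed it
        hi = 255.0 if arr.max() <= 255 else 65535.0
    else:
        raise ValueError(f"unsupported pixel dtype {arr.dtype}; use 8- or 16-bit images")
    return GreyImage(arr.astype(np.float64), 0.0, hi)


def quantize(img: GreyImage, bitdepth: int) -> np.ndarray:
    """Round half away from zero and clip to the display range."""
    if bitdepth not in (8, 16):
        raise ValueError("bitdepth must be 8 or 16")
    p = img.pixels
    rounded = np.copysign(np.floor(np.abs(p) + 0.5), p)
    clipped = np.clip(rounded, img.display_min, img.display_max)
    return clipped.astype(np.uint8 if bitdepth == 8 else np.uint16)


def write_image(img: GreyImage, path: str, bitdepth: int | None = None) -> None:
    """Quantize and write to a lossless format (PNG/TIFF/PGM).

    ``bitdepth`` defaults to the depth implied by the display range (16 if
    display_max exceeds 255, else 8).
    """
    ext = os.path.splitext(path)[1].lower()
    if ext in _LOSSY:
        raise ValueError(f"{ext} is lossy; write PNG, TIFF or PGM instead")
    if ext not in _SUPPORTED:
        raise ValueError(
            f"unsupported format {ext!r}; supported formats are PNG, TIFF and PGM"
        )
    if bitdepth is None:
        bitdepth = 16 if img.display_max > 255 else 8
    iio.imwrite(path, quantize(img, bitdepth))
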