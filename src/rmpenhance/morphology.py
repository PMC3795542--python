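"""Flat greyscale mathematical morphology.

The four basic operators — dilation, erosion, opening, closing — with flat
(binary) structuring elements, plus structuring-element construction.

Conventions
-----------
Images are 2-D real-valued rasters carried by :class:`GreyImage`.  A
structuring element (SE) is a binary mask with a distinguished origin; the
offsets of its true cells relative to the origin define the probe
neighbourhood.  Dilation takes the pixelwise maximum of ``f(x - b)`` over SE
offsets ``b`` (erosion the minimum of ``f(x + b)``), the adjunction pair, so
that ``opening = dilate(erode(f))`` and ``closing = erode(dilate(f))`` with
the *same* SE are anti-extensive/extensive and idempotent for any SE,
symmetric or not.

Out-of-frame samples are supplied by edge replication.  This border rule
avoids spurious top-hat responses along the frame, and is fixed: every
operator (and the phantom pipeline built on top) uses it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi

__all__ = [
    "GreyImage",
    "StructuringElement",
    "make_structuring_element",
    "dilate",
    "erode",
    "opening",
    "closing",
]


@dataclass(frozen=True)
class GreyImage:
    """A 2-D greyscale raster with a declared display range.

    Pixel values are held as float64 regardless of the source bit depth;
    quantization back to integers happens only on write-out.  The display
    range (e.g. ``[0, 255]`` for 8-bit material) tells range-dependent
    operations (histogram equalization, stretching, clipping) what "full
    scale" means — pixel values may transiently leave it during processing.
    """

    pixels: np.ndarray
    display_min: float = 0.0
    display_max: float = 255.0

    def __post_init__(self) -> None:
        arr = np.asarray(self.pixels, dtype=np.float64)
        if arr.ndim != 2 or arr.shape[0] < 1 or arr.shape[1] < 1:
            raise ValueError("GreyImage requires a 2-D array with H, W >= 1")
        if not np.all(np.isfinite(arr)):
            raise ValueError("GreyImage pixels must all be finite")
        if not self.display_min < self.display_max:
            raise ValueError("display_min must be strictly below display_max")
        object.__setattr__(self, "pixels", arr)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    def with_pixels(self, pixels: np.ndarray) -> "GreyImage":
        """A new image with the same display range and new pixel data."""
        return GreyImage(pixels, self.display_min, self.display_max)

    def __array__(self, dtype=None, copy=None) -> np.ndarray:
        if dtype is not None:
            return self.pixels.astype(dtype)
        return self.pixels


def as_image(f, display_min: float = 0.0, display_max: float = 255.0) -> GreyImage:
    """Coerce an array or GreyImage to a GreyImage (default 8-bit range)."""
    if isinstance(f, GreyImage):
        return f
    return GreyImage(np.asarray(f, dtype=np.float64), display_min, display_max)


@dataclass(frozen=True)
class StructuringElement:
    """A flat binary structuring element with an origin.

    ``mask`` is the probe shape, ``origin`` the (row, col) index of the cell
    whose offset is (0, 0).  Disc and square SEs are symmetric under 180°
    rotation about the origin; centred lines through the origin are too.
    """

    mask: np.ndarray
    origin: tuple[int, int]
    shape_tag: str = "custom"
    size_param: int = 0
    angle: float | None = None

    def __post_init__(self) -> None:
        mask = np.asarray(self.mask, dtype=bool)
        if mask.ndim != 2 or not mask.any():
            raise ValueError("structuring element mask must be 2-D with at least one true cell")
        r, c = self.origin
        if not (0 <= r < mask.shape[0] and 0 <= c < mask.shape[1]):
            raise ValueError("structuring element origin must lie within the mask bounds")
        if self.shape_tag in ("disc", "square"):
            if not np.array_equal(mask, mask[::-1, ::-1]):
                raise ValueError(f"{self.shape_tag} structuring element must be 180°-symmetric")
        object.__setattr__(self, "mask", mask)

    @property
    def offsets(self) -> np.ndarray:
        """(k, 2) array of true-cell offsets relative to the origin."""
        rr, cc = np.nonzero(self.mask)
        return np.stack([rr - self.origin[0], cc - self.origin[1]], axis=1)

    def reflected(self) -> "StructuringElement":
        """The 180°-rotated SE (the transpose set B̌)."""
        h, w = self.mask.shape
        return StructuringElement(
            self.mask[::-1, ::-1],
            (h - 1 - self.origin[0], w - 1 - self.origin[1]),
            shape_tag="custom",
            size_param=self.size_param,
            angle=self.angle,
        )


def make_structuring_element(
    shape_tag: str, size_param: int, angle: float | None = None
) -> StructuringElement:
    """Build a disc, square or line structuring element.

    Parameters
    ----------
    shape_tag
        One of ``disc``, ``square``, ``line``.
    size_param
        Disc diameter / square side / line length, in pixels.  Disc and
        square sizes must be odd so the origin sits on a pixel centre.
    angle
        Orientation in radians, measured from the row direction toward
        increasing column index.  Only meaningful (and only accepted) for
        ``line``.

    The disc is the digital Euclidean disc: cells whose centre lies within
    ``(size_param - 1) / 2`` of the origin.  The line is a 1-pixel-wide
    Bresenham segment of ``size_param`` pixels through the origin.
    """
    if size_param < 1:
        raise ValueError("size_param must be >= 1")
    if shape_tag in ("disc", "square"):
        if angle is not None:
            raise ValueError(f"angle applies only to line structuring elements, not {shape_tag}")
        if size_param % 2 == 0:
            raise ValueError(
                f"{shape_tag} structuring elements require an odd size_param so the "
                f"origin is a pixel centre; got {size_param}"
            )
        half = (size_param - 1) // 2
        if shape_tag == "square":
            mask = np.ones((size_param, size_param), dtype=bool)
        else:
            yy, xx = np.mgrid[-half : half + 1, -half : half + 1]
            mask = yy * yy + xx * xx <= half * half
        return StructuringElement(mask, (half, half), shape_tag, size_param)
    if shape_tag == "line":
        theta = 0.0 if angle is None else float(angle)
        half = (size_param - 1) / 2.0
        er = int(round(half * np.sin(theta)))
        ec = int(round(half * np.cos(theta)))
        pts = _bresenham(-er, -ec, er, ec)
        rows = [p[0] for p in pts]
        cols = [p[1] for p in pts]
        rmin, cmin = min(rows), min(cols)
        mask = np.zeros((max(rows) - rmin + 1, max(cols) - cmin + 1), dtype=bool)
        for r, c in pts:
            mask[r - rmin, c - cmin] = True
        return StructuringElement(mask, (-rmin, -cmin), "line", size_param, theta)
    raise ValueError(f"unknown structuring element shape {shape_tag!r}; use disc, square or line")


def _bresenham(r0: int, c0: int, r1: int, c1: int) -> list[tuple[int, int]]:
    dr, dc = abs(r1 - r0), abs(c1 - c0)
    sr = 1 if r1 >= r0 else -1
    sc = 1 if c1 >= c0 else -1
    err = dc - dr
    pts = []
    r, c = r0, c0
    while True:
        pts.append((r, c))
        if r == r1 and c == c1:
            break
        e2 = 2 * err
        if e2 > -dr:
            err -= dr
            c += sc
        if e2 < dc:
            err += dc
            r += sr
    return pts


def _filter_args_dilate(B: StructuringElement):
    # dilation: out(x) = max_b f(x - b); maximum_filter computes
    # max over f(x + k - centre - origin), so pass the flipped mask and shift
    # the effective centre onto the flipped origin.
    h, w = B.mask.shape
    fp = B.mask[::-1, ::-1]
    origin = (h - 1 - B.origin[0] - h // 2, w - 1 - B.origin[1] - w // 2)
    return fp, origin


def _filter_args_erode(B: StructuringElement):
    # erosion: out(x) = min_b f(x + b); pass the mask as-is, centre on origin.
    h, w = B.mask.shape
    return B.mask, (B.origin[0] - h // 2, B.origin[1] - w // 2)


def dilate(f, B: StructuringElement) -> GreyImage:
    """Flat dilation: pixelwise maximum of ``f(x - b)`` over SE offsets."""
    img = as_image(f)
    fp, origin = _filter_args_dilate(B)
    out = ndi.maximum_filter(img.pixels, footprint=fp, mode="nearest", origin=origin)
    return img.with_pixels(out)


def erode(f, B: StructuringElement) -> GreyImage:
    """Flat erosion: pixelwise minimum of ``f(x + b)`` over SE offsets."""
    img = as_image(f)
    fp, origin = _filter_args_erode(B)
    out = ndi.minimum_filter(img.pixels, footprint=fp, mode="nearest", origin=origin)
    return img.with_pixels(out)


def opening(f, B: StructuringElement) -> GreyImage:
    """Erosion followed by dilation (adjunction pair): removes bright
    structures smaller than the SE; anti-extensive and idempotent."""
    return dilate(erode(f, B), B)


def closing(f, B: StructuringElement) -> GreyImage:
    """Dilation followed by erosion: fills dark structures smaller than the
    SE; extensive and idempotent; the dual of opening."""
    return erode(dilate(f, B), B)
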