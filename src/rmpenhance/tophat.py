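"""Top-hat transforms, conventional and RMP-based.

The white top-hat (WTH) is the image minus its opening: it extracts bright
structures smaller than the structuring element, independently of the local
background level.  The black top-hat (BTH) is the closing minus the image
and extracts dark structures the same way.  Passing a :class:`RotationSet`
swaps the conventional opening/closing for their rotational (RMP) variants;
with N = 1 the two coincide exactly.

The top-hat contrast operator κ adds WTH to the image and subtracts BTH,
brightening small bright targets and darkening small dark ones at once.
"""

from __future__ import annotations

import numpy as np

from .morphology import GreyImage, StructuringElement, as_image, closing, opening
from .rmp import RotationSet, rmp_closing, rmp_opening

__all__ = ["white_tophat", "black_tophat", "tophat_contrast"]


def white_tophat(f, B: StructuringElement, R: RotationSet | None = None) -> GreyImage:
    """f minus its (RMP) opening; nonnegative bright-structure residue.

    Interpolated RMP branches can exceed f by sub-quantum amounts, so
    negative residues are clamped to zero: the transform's output is an
    image of extracted structure and must be nonnegative.
    """
    img = as_image(f)
    opened = opening(img, B) if R is None else rmp_opening(img, B, R)
    return img.with_pixels(np.maximum(img.pixels - opened.pixels, 0.0))


def black_tophat(f, B: StructuringElement, R: RotationSet | None = None) -> GreyImage:
    """(RMP) closing minus f; nonnegative dark-structure residue."""
    img = as_image(f)
    closed = closing(img, B) if R is None else rmp_closing(img, B, R)
    return img.with_pixels(np.maximum(closed.pixels - img.pixels, 0.0))


def tophat_contrast(f, B: StructuringElement, R: RotationSet | None = None) -> GreyImage:
    """The top-hat contrast operator κ = f + WTH − BTH (κ′ when R given).

    The output is not range-limited here; the full enhancement operator
    handles the display range after greyscale modification.
    """
    img = as_image(f)
    wth = white_tophat(img, B, R)
    bth = black_tophat(img, B, R)
    return img.with_pixels(img.pixels + wth.pixels - bth.pixels)
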