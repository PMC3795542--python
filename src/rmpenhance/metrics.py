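"""Local contrast and the contrast improvement ratio (CIR).

Local contrast at a pixel compares the mean intensity p of a small centred
square window (side R_C) against the mean a of the surrounding annulus — the
R_N window minus the R_C window:

    C(x, y) = |p − a| / (p + a)        (0 when p + a = 0),

a value in [0, 1].  The CIR of an enhanced image against its original is

    CIR = Σ_R (C − C̃)² / Σ_R C²,

with C from the original, C̃ from the enhanced image, summed over a region
of interest R (by default every pixel whose R_N window fits in the frame).
A larger CIR means the enhancement changed the local target/surround
separation more, relative to the contrast originally present.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .morphology import GreyImage, as_image

__all__ = ["CIRConfig", "DegenerateContrastError", "local_contrast_map", "cir"]


class DegenerateContrastError(ValueError):
    """The original image has no local contrast on the evaluation region,
    so the CIR denominator is zero and the ratio is undefined."""


@dataclass(frozen=True)
class CIRConfig:
    """Window geometry of the local-contrast measurement.

    rc, rn
        Odd side lengths of the centre and neighbourhood square windows
        (defaults 11 and 41).
    region
        Optional boolean mask selecting the region of interest R; it is
        intersected with the interior where the R_N window fits.  ``None``
        means the whole valid interior.
    """

    rc: int = 11
    rn: int = 41
    region: np.ndarray | None = None

    def __post_init__(self) -> None:
        if not (1 <= self.rc < self.rn):
            raise ValueError("need 1 <= rc < rn")
        if self.rc % 2 == 0 or self.rn % 2 == 0:
            raise ValueError("rc and rn must both be odd")


def _window_mean(a: np.ndarray, k: int) -> np.ndarray:
    return sliding_window_view(a, (k, k)).mean(axis=(-2, -1))


def valid_interior(shape: tuple[int, int], cfg: CIRConfig) -> np.ndarray:
    """Mask of pixels whose R_N window lies fully inside the frame."""
    h, w = shape
    half = cfg.rn // 2
    mask = np.zeros(shape, dtype=bool)
    mask[half : h - half, half : w - half] = True
    return mask


def local_contrast_map(f, cfg: CIRConfig | None = None) -> GreyImage:
    """Per-pixel local contrast C; zero outside the valid interior."""
    cfg = cfg or CIRConfig()
    img = as_image(f)
    h, w = img.shape
    if h < cfg.rn or w < cfg.rn:
        raise ValueError(
            f"image {h}x{w} is smaller than the {cfg.rn}x{cfg.rn} neighbourhood window"
        )
    off = (cfg.rn - cfg.rc) // 2
    mean_rc = _window_mean(img.pixels, cfg.rc)
    mean_rn = _window_mean(img.pixels, cfg.rn)
    p = mean_rc[off : off + mean_rn.shape[0], off : off + mean_rn.shape[1]]
    n_ann = cfg.rn * cfg.rn - cfg.rc * cfg.rc
    a = (mean_rn * (cfg.rn * cfg.rn) - p * (cfg.rc * cfg.rc)) / n_ann
    denom = p + a
    with np.errstate(invalid="ignore", divide="ignore"):
        c = np.where(denom > 0, np.abs(p - a) / denom, 0.0)
    out = np.zeros((h, w))
    half = cfg.rn // 2
    out[half : half + c.shape[0], half : half + c.shape[1]] = c
    return GreyImage(out, 0.0, 1.0)


def cir(original, enhanced, cfg: CIRConfig | None = None) -> float:
    """Contrast improvement ratio of ``enhanced`` against ``original``."""
    cfg = cfg or CIRConfig()
    orig = as_image(original)
    enh = as_image(enhanced)
    if orig.shape != enh.shape:
        raise ValueError("original and enhanced images must have the same shape")
    c0 = local_contrast_map(orig, cfg).pixels
    c1 = local_contrast_map(enh, cfg).pixels
    region = valid_interior(orig.shape, cfg)
    if cfg.region is not None:
        region = region & np.asarray(cfg.region, dtype=bool)
    den = float(np.sum(c0[region] ** 2))
    if den == 0.0:
        raise DegenerateContrastError(
            "original image has zero local contrast on the evaluation region; CIR undefined"
        )
    num = float(np.sum((c0[region] - c1[region]) ** 2))
    return num / den
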