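"""Greyscale modification and the full enhancement operator λ.

Top-hat residues of low-contrast targets are themselves low-amplitude; added
back to the image as-is they barely change it.  The remedy is a greyscale
modification ν applied to each top-hat image before recombination:
histogram equalization (flattening the residue's intensity distribution)
followed by linear contrast stretching to the full display range.  The
enhancement operator is then

    λ(f) = f + ν(WTH′(f)) − ν(BTH′(f)),

with WTH′/BTH′ the RMP top-hats, and the result restricted to the display
range.  "Restricted" is read as saturation clipping by default — clipping
preserves the absolute enhancement of mid-range structure instead of
remapping the whole image — with a rescale mode available.

A featureless (constant) top-hat contributes nothing: ν maps it to zeros.
Without this rule the constant→display_max equalization convention would
inject a global offset into λ, so λ of a constant image would not be the
identity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .morphology import GreyImage, as_image, make_structuring_element
from .rmp import RotationSet, default_direction_count, rmp_closing, rmp_opening
from .tophat import black_tophat, white_tophat

__all__ = [
    "EnhanceConfig",
    "histogram_equalize",
    "linear_stretch",
    "greyscale_modify",
    "presmooth",
    "enhance_lambda",
]


@dataclass(frozen=True)
class EnhanceConfig:
    """Parameters of the λ operator.

    se_shape, se_size
        Structuring element of the top-hats.  The default disc of diameter
        31 px is sized to exceed the base diameter of the targets to be
        enhanced — the SE must be larger than a structure for the top-hat
        to extract it.
    n_rot
        Number of RMP directions; ``None`` selects the per-shape default
        (8 for disc/square, 36 for line).
    out_min, out_max
        Display range λ's output is restricted to.
    range_mode
        ``clip`` (default, saturation) or ``rescale`` (min–max stretch).
    presmooth
        Apply RMP opening-then-closing with a small disc first, as an
        edge-preserving noise reduction; off by default, for use on noisy
        acquisitions where top-hats would amplify the noise.
    """

    se_shape: str = "disc"
    se_size: int = 31
    n_rot: int | None = None
    out_min: float = 0.0
    out_max: float = 255.0
    presmooth: bool = False
    presmooth_size: int = 3
    hist_bins: int = 256
    range_mode: str = "clip"
    interpolation: str = "bilinear"

    def __post_init__(self) -> None:
        if self.se_shape in ("disc", "square") and (self.se_size < 3 or self.se_size % 2 == 0):
            raise ValueError("disc/square se_size must be odd and >= 3")
        if self.n_rot is not None and self.n_rot < 1:
            raise ValueError("n_rot must be >= 1")
        if not self.out_min < self.out_max:
            raise ValueError("out_min must be below out_max")
        if self.hist_bins < 2:
            raise ValueError("hist_bins must be >= 2")
        if self.range_mode not in ("clip", "rescale"):
            raise ValueError("range_mode must be clip or rescale")

    @property
    def effective_n(self) -> int:
        return self.n_rot if self.n_rot is not None else default_direction_count(self.se_shape)


def histogram_equalize(g, bins: int = 256) -> GreyImage:
    """CDF remap of the display range over ``bins`` levels.

    out = display_min + (display_max − display_min) · cdf(level), with the
    CDF including each level's own bin, so the top occupied level maps to
    display_max (and a constant image maps entirely to display_max).
    Monotone non-decreasing in the input level.
    """
    img = as_image(g)
    if bins < 2:
        raise ValueError("bins must be >= 2")
    span = img.display_max - img.display_min
    levels = np.clip(
        ((img.pixels - img.display_min) / span * bins).astype(np.int64), 0, bins - 1
    )
    hist = np.bincount(levels.ravel(), minlength=bins)
    cdf = np.cumsum(hist) / levels.size
    out = img.display_min + span * cdf[levels]
    return img.with_pixels(out)


def linear_stretch(g) -> GreyImage:
    """Min–max stretch to the display range.

    A constant image has no range to stretch; it maps to display_min (a
    flat image carries no structure, and downstream ν must not inject an
    offset).
    """
    img = as_image(g)
    lo = img.pixels.min()
    hi = img.pixels.max()
    if hi == lo:
        return img.with_pixels(np.full_like(img.pixels, img.display_min))
    span = img.display_max - img.display_min
    # divide before scaling so min/max land exactly on the display bounds
    out = (img.pixels - lo) / (hi - lo) * span + img.display_min
    return img.with_pixels(out)


def greyscale_modify(tophat_img, bins: int = 256) -> GreyImage:
    """The ν operator: equalize then stretch a top-hat image.

    A constant (typically all-zero) top-hat returns all zeros — a
    featureless residue must contribute nothing to λ.  Negative inputs are
    rejected: they indicate a violated top-hat contract upstream.
    """
    img = as_image(tophat_img)
    if (img.pixels < 0).any():
        raise ValueError("greyscale_modify expects a nonnegative top-hat image")
    if img.pixels.max() == img.pixels.min():
        return img.with_pixels(np.zeros_like(img.pixels))
    return linear_stretch(histogram_equalize(img, bins))


def presmooth(f, cfg: EnhanceConfig) -> GreyImage:
    """Edge-preserving noise reduction: RMP opening then RMP closing with a
    small disc (default diameter 3)."""
    img = as_image(f)
    B = make_structuring_element("disc", cfg.presmooth_size)
    R = RotationSet(cfg.effective_n, cfg.interpolation)
    return rmp_closing(rmp_opening(img, B, R), B, R)


def enhance_lambda(f, cfg: EnhanceConfig | None = None) -> GreyImage:
    """The full contrast enhancement operator λ.

    Computes the RMP white and black top-hats with the configured SE and
    direction count, greyscale-modifies each (ν), recombines as
    f + ν_WTH′ − ν_BTH′, and restricts the result to the display range.
    Deterministic: identical input and config give bit-identical output.
    """
    cfg = cfg or EnhanceConfig()
    img = as_image(f)
    if cfg.presmooth:
        img = presmooth(img, cfg)
    B = make_structuring_element(
        cfg.se_shape, cfg.se_size, 0.0 if cfg.se_shape == "line" else None
    )
    R = RotationSet(cfg.effective_n, cfg.interpolation)
    wth = white_tophat(img, B, R)
    bth = black_tophat(img, B, R)
    nu_w = greyscale_modify(wth, cfg.hist_bins)
    nu_b = greyscale_modify(bth, cfg.hist_bins)
    lam = img.pixels + nu_w.pixels - nu_b.pixels
    if cfg.range_mode == "clip":
        out = np.clip(lam, cfg.out_min, cfg.out_max)
        return GreyImage(out, cfg.out_min, cfg.out_max)
    return linear_stretch(GreyImage(lam, cfg.out_min, cfg.out_max))
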