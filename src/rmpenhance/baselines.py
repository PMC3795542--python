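"""Comparison baselines: multiscale retinex and CLAHE.

Two widely used general-purpose contrast enhancers, provided so the
morphological method can be benchmarked on the same inputs with the same
metric.

Multiscale retinex (MSR) forms, at each of several Gaussian scales, the
difference between the image and its blurred version in the logarithmic
domain, and averages the scales with given weights; the raw log-domain
response is mapped to the display range by a min–max stretch.

CLAHE (contrast-limited adaptive histogram equalization) equalizes small
tiles independently — with each tile's histogram clipped and the clipped
excess redistributed uniformly, limiting noise amplification — and blends
the per-tile mappings bilinearly between tile centres.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage as ndi

from .enhancement import linear_stretch
from .morphology import GreyImage, as_image

__all__ = ["msr", "clahe"]


def msr(
    f,
    sigmas: tuple[float, ...] = (5.0, 15.0, 25.0),
    weights: tuple[float, ...] | None = None,
) -> GreyImage:
    """Multiscale retinex with Gaussian surrounds.

    out_raw = Σ_k w_k · [log(f + 1) − log(G_σk ⊛ f + 1)], stretched to the
    display range.  Defaults: scales 5, 15, 25 px with weight 1/3 each.
    """
    img = as_image(f)
    sigmas = tuple(float(s) for s in sigmas)
    if weights is None:
        weights = tuple(1.0 / len(sigmas) for _ in sigmas)
    weights = tuple(float(w) for w in weights)
    if len(sigmas) != len(weights) or len(sigmas) < 1:
        raise ValueError("sigmas and weights must be equal-length, non-empty lists")
    if abs(sum(weights) - 1.0) > 1e-9:
        raise ValueError("weights must sum to 1")
    logf = np.log(img.pixels + 1.0)
    raw = np.zeros_like(img.pixels)
    for s, w in zip(sigmas, weights):
        blurred = ndi.gaussian_filter(img.pixels, sigma=s, mode="nearest")
        raw += w * (logf - np.log(blurred + 1.0))
    return linear_stretch(img.with_pixels(raw))


def _equalize_lut(
    values: np.ndarray,
    display_min: float,
    display_max: float,
    bins: int,
    clip_count: float | None,
) -> np.ndarray:
    """Level→output lookup table for one tile: histogram (optionally clipped,
    excess spread uniformly), CDF, remap over the display range."""
    span = display_max - display_min
    levels = np.clip(((values - display_min) / span * bins).astype(np.int64), 0, bins - 1)
    hist = np.bincount(levels.ravel(), minlength=bins).astype(np.float64)
    if clip_count is not None:
        excess = np.maximum(hist - clip_count, 0.0).sum()
        hist = np.minimum(hist, clip_count) + excess / bins
    cdf = np.cumsum(hist) / hist.sum()
    return display_min + span * cdf


def clahe(f, block: int = 9, clip_limit: float = 0.01, bins: int = 256) -> GreyImage:
    """Contrast-limited adaptive histogram equalization.

    ``block`` is the tile side in pixels (default 9); ``clip_limit`` is the
    per-bin clip ceiling as a fraction of the tile pixel count (default
    0.01, floored at one count so tiny tiles keep a usable histogram).
    With a single tile and a clip limit high enough to clip nothing, the
    result equals plain whole-image histogram equalization.
    """
    img = as_image(f)
    h, w = img.shape
    if block < 2:
        raise ValueError("block must be >= 2")
    if block > h or block > w:
        raise ValueError(f"block {block} exceeds image size {h}x{w}")
    if clip_limit <= 0:
        raise ValueError("clip_limit must be > 0")
    nt_r = -(-h // block)
    nt_c = -(-w // block)
    bounds_r = [(i * block, min((i + 1) * block, h)) for i in range(nt_r)]
    bounds_c = [(j * block, min((j + 1) * block, w)) for j in range(nt_c)]
    luts = np.empty((nt_r, nt_c, bins))
    for i, (r0, r1) in enumerate(bounds_r):
        for j, (c0, c1) in enumerate(bounds_c):
            tile = img.pixels[r0:r1, c0:c1]
            clip_count = max(clip_limit * tile.size, 1.0)
            luts[i, j] = _equalize_lut(
                tile, img.display_min, img.display_max, bins, clip_count
            )
    span = img.display_max - img.display_min
    levels = np.clip(((img.pixels - img.display_min) / span * bins).astype(np.int64), 0, bins - 1)

    centres_r = np.array([(r0 + r1 - 1) / 2.0 for r0, r1 in bounds_r])
    centres_c = np.array([(c0 + c1 - 1) / 2.0 for c0, c1 in bounds_c])
    i1 = np.clip(np.searchsorted(centres_r, np.arange(h)), 0, nt_r - 1)
    i0 = np.clip(i1 - 1, 0, nt_r - 1)
    j1 = np.clip(np.searchsorted(centres_c, np.arange(w)), 0, nt_c - 1)
    j0 = np.clip(j1 - 1, 0, nt_c - 1)
    dr = centres_r[i1] - centres_r[i0]
    wr = np.where(dr > 0, (np.arange(h) - centres_r[i0]) / np.where(dr > 0, dr, 1.0), 0.0)
    wr = np.clip(wr, 0.0, 1.0)
    dc = centres_c[j1] - centres_c[j0]
    wc = np.where(dc > 0, (np.arange(w) - centres_c[j0]) / np.where(dc > 0, dc, 1.0), 0.0)
    wc = np.clip(wc, 0.0, 1.0)

    I0 = i0[:, None] * np.ones(w, dtype=int)
    I1 = i1[:, None] * np.ones(w, dtype=int)
    J0 = np.ones(h, dtype=int)[:, None] * j0
    J1 = np.ones(h, dtype=int)[:, None] * j1
    WR = wr[:, None]
    WC = wc[None, :]
    out = (
        (1 - WR) * (1 - WC) * luts[I0, J0, levels]
        + (1 - WR) * WC * luts[I0, J1, levels]
        + WR * (1 - WC) * luts[I1, J0, levels]
        + WR * WC * luts[I1, J1, levels]
    )
    return img.with_pixels(out)
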