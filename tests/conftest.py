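"""Shared fixtures and independent brute-force oracles.

The oracles deliberately avoid the package's fast paths: windowed extrema
are computed per pixel with clipped (edge-replicated) indexing, and the CIR
oracle loops over pixels taking plain window means.
"""

from __future__ import annotations

import numpy as np
import pytest

from rmpenhance.morphology import StructuringElement


def oracle_dilate(a: np.ndarray, se: StructuringElement) -> np.ndarray:
    """max over SE offsets b of f(x - b), edge replicated."""
    h, w = a.shape
    offs = se.offsets
    out = np.empty_like(a, dtype=float)
    for x in range(h):
        rr = np.clip(x - offs[:, 0], 0, h - 1)
        for y in range(w):
            cc = np.clip(y - offs[:, 1], 0, w - 1)
            out[x, y] = a[rr, cc].max()
    return out


def oracle_erode(a: np.ndarray, se: StructuringElement) -> np.ndarray:
    """min over SE offsets b of f(x + b), edge replicated."""
    h, w = a.shape
    offs = se.offsets
    out = np.empty_like(a, dtype=float)
    for x in range(h):
        rr = np.clip(x + offs[:, 0], 0, h - 1)
        for y in range(w):
            cc = np.clip(y + offs[:, 1], 0, w - 1)
            out[x, y] = a[rr, cc].min()
    return out


def oracle_local_contrast(a: np.ndarray, rc: int, rn: int) -> np.ndarray:
    """Nested-loop local contrast map |p - a| / (p + a), zero-padded frame."""
    h, w = a.shape
    hc, hn = rc // 2, rn // 2
    out = np.zeros((h, w))
    for x in range(hn, h - hn):
        for y in range(hn, w - hn):
            centre = a[x - hc : x + hc + 1, y - hc : y + hc + 1]
            big = a[x - hn : x + hn + 1, y - hn : y + hn + 1]
            p = centre.mean()
            ann = (big.sum() - centre.sum()) / (rn * rn - rc * rc)
            out[x, y] = abs(p - ann) / (p + ann) if p + ann > 0 else 0.0
    return out


def oracle_cir(orig: np.ndarray, enh: np.ndarray, rc: int, rn: int) -> float:
    c0 = oracle_local_contrast(orig, rc, rn)
    c1 = oracle_local_contrast(enh, rc, rn)
    hn = rn // 2
    sel = np.zeros(orig.shape, dtype=bool)
    sel[hn : orig.shape[0] - hn, hn : orig.shape[1] - hn] = True
    return float(np.sum((c0[sel] - c1[sel]) ** 2) / np.sum(c0[sel] ** 2))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def default_phantom():
    from rmpenhance.synthetic import generate_phantom

    return generate_phantom()
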