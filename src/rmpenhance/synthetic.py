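"""Synthetic low-contrast phantoms.

The generator emulates the kind of test scene the method is meant for:
several low-contrast bright blobs of differing mean intensity sitting on a
spatially uneven background, with optional additive Gaussian noise — a
stand-in for a mass or nodule on unevenly illuminated tissue.  It also
returns the binary mask of blob supports, so contrast metrics can be
restricted to the targets.

The default phantom is 218 × 238 pixels (8-bit range) with six flat-disc
targets of radius 10–13 px and amplitude 10–30 grey levels over a base of
100, a left-to-right background ramp of 40 levels, and noise σ = 2.  Target
diameters stay below the default 31-px enhancement disc — the structuring
element must exceed the target base diameter for the top-hat to extract it.
Blob geometry is fixed by the PhantomSpec; the seed drives only the noise,
so different seeds are independent noise realisations of the same scene.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .morphology import GreyImage

__all__ = ["Blob", "PhantomSpec", "generate_phantom", "DEFAULT_BLOBS"]


@dataclass(frozen=True)
class Blob:
    """A flat-disc bright target: centre (row, col), radius in px, and
    amplitude in grey levels above the local background."""

    center: tuple[float, float]
    radius: float
    amplitude: float


#: Six low-contrast targets spread over the frame, radii 10–13 px
#: (diameters 21–27, all below the default 31-px disc SE), amplitudes
#: 10–30 grey levels (≤ 12% of the 8-bit range).
DEFAULT_BLOBS: tuple[Blob, ...] = (
    Blob((52, 48), 12, 30.0),
    Blob((60, 150), 13, 22.0),
    Blob((110, 82), 10, 15.0),
    Blob((120, 192), 12, 28.0),
    Blob((168, 58), 13, 18.0),
    Blob((165, 160), 11, 10.0),
)


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of the generated scene.

    gradient is the total background change (grey levels) across the full
    height and width respectively; modulation_amp adds a low-frequency
    sinusoidal unevenness (off by default).  noise_sigma is the additive
    Gaussian noise standard deviation; seed feeds the noise generator only.
    """

    height: int = 218
    width: int = 238
    blobs: tuple[Blob, ...] = DEFAULT_BLOBS
    base: float = 100.0
    gradient: tuple[float, float] = (0.0, 40.0)
    modulation_amp: float = 0.0
    noise_sigma: float = 2.0
    seed: int = 0
    display_min: float = 0.0
    display_max: float = 255.0

    def __post_init__(self) -> None:
        if self.height < 1 or self.width < 1:
            raise ValueError("phantom needs positive dimensions")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        for b in self.blobs:
            r, c = b.center
            if not (
                b.radius <= r <= self.height - 1 - b.radius
                and b.radius <= c <= self.width - 1 - b.radius
            ):
                raise ValueError(f"blob at {b.center} (radius {b.radius}) leaves the frame")


def generate_phantom(spec: PhantomSpec | None = None) -> tuple[GreyImage, np.ndarray]:
    """Render the phantom; returns (image, boolean target mask).

    The image is background + gradient + modulation + flat-disc blobs +
    seeded Gaussian noise, clipped to the display range.  Bit-identical
    across runs for a fixed spec.
    """
    spec = spec or PhantomSpec()
    h, w = spec.height, spec.width
    rows = np.arange(h)[:, None]
    cols = np.arange(w)[None, :]
    bg = spec.base + np.zeros((h, w))
    if h > 1:
        bg = bg + spec.gradient[0] * (rows / (h - 1))
    if w > 1:
        bg = bg + spec.gradient[1] * (cols / (w - 1))
    if spec.modulation_amp:
        bg = bg + spec.modulation_amp * np.sin(2 * np.pi * rows / h) * np.cos(
            2 * np.pi * cols / w
        )
    img = bg
    mask = np.zeros((h, w), dtype=bool)
    for b in spec.blobs:
        d2 = (rows - b.center[0]) ** 2 + (cols - b.center[1]) ** 2
        disc = d2 <= b.radius**2
        img = img + b.amplitude * disc
        mask |= disc
    if spec.noise_sigma > 0:
        rng = np.random.default_rng(spec.seed)
        img = img + rng.normal(0.0, spec.noise_sigma, size=(h, w))
    img = np.clip(img, spec.display_min, spec.display_max)
    return GreyImage(img, spec.display_min, spec.display_max), mask
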