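# rmpenhance

Contrast enhancement for greyscale biomedical images — mammograms, chest
radiographs, micrographs — by **rotational morphological processing (RMP)**
top-hat transforms, with a quantitative quality metric and two standard
baselines for comparison.

## The method

Low-contrast targets (a mass in a mammogram, a nodule in a chest film) sit
on uneven backgrounds that defeat global enhancement. Greyscale morphology
handles this selectively: with a flat structuring element *B*, the white
top-hat `WTH(f) = f − γ_B(f)` (image minus opening) extracts bright
structures smaller than *B* independently of the background level, and the
black top-hat `BTH(f) = φ_B(f) − f` (closing minus image) extracts dark
ones.

Two refinements make the operator effective:

1. **RMP.** A structuring element applied in one fixed raster direction
   leaves SE-shaped artefacts on structures with other orientations. RMP
   rotates the *image* through N directions θᵢ = πi/N spanning a half
   circle, opens (or closes) each rotated copy with the same SE, derotates,
   and fuses the N aligned results with a pixelwise max (opening) or min
   (closing). N = 1 recovers the conventional operators; N = 8 suffices for
   disc/square SEs, N = 36 for lines. The RMP top-hats WTH′/BTH′ are built
   from these fused operators.
2. **Greyscale modification ν.** Top-hat residues of low-contrast targets
   are too small to matter when added back. Each top-hat image is therefore
   histogram-equalized and then linearly stretched to the full display
   range before recombination.

The enhancement operator is

```
λ(f) = f + ν(WTH′(f)) − ν(BTH′(f)),
```

restricted to the display range (saturation clipping by default).

Enhancement quality is measured by the **contrast improvement ratio**: with
local contrast `C = |p − a| / (p + a)` (p = mean of an R_C×R_C centre
window, a = mean of the surrounding R_N×R_N annulus),

```
CIR = Σ_R (C − C̃)² / Σ_R C²,
```

C from the original and C̃ from the enhanced image. Multiscale retinex
(MSR) and CLAHE are included as comparison baselines, and a synthetic
phantom generator (low-contrast discs on a ramped, noisy background)
makes the whole pipeline testable without any image downloads.

## Worked example

```python
from rmpenhance import (EnhanceConfig, PhantomSpec, cir, clahe,
                        enhance_lambda, generate_phantom, msr)

img, mask = generate_phantom(PhantomSpec(seed=1))   # 218x238, six blobs
enhanced = enhance_lambda(img, EnhanceConfig())     # disc-31 SE, N=8
print(f"CIR proposed: {cir(img, enhanced):.3f}")
print(f"CIR MSR:      {cir(img, msr(img)):.3f}")
print(f"CIR CLAHE:    {cir(img, clahe(img, block=9)):.3f}")
```

prints

```
CIR proposed: 37.048
CIR MSR:      19.467
CIR CLAHE:    0.161
```

The RMP operator separates the six targets far more strongly than either
baseline: its ν-modified top-hats push each blob toward a distinct, nearly
homogeneous intensity band, which is exactly what the windowed CIR rewards.
CLAHE barely moves the metric because its tile-clipped equalization spreads
enhancement over the background as much as over the targets.

The same pipeline is available from the shell:

```sh
rmpenhance synth --out phantom.png --mask mask.png --seed 1
rmpenhance enhance phantom.png --out enhanced.png --se disc --size 31
rmpenhance cir phantom.png enhanced.png --rc 11 --rn 41
rmpenhance baseline phantom.png --method msr --out msr.png
```

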