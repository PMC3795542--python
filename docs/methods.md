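# Methods

## Model and procedure

The package enhances low-contrast targets in 2-D greyscale images by a
three-stage morphological operator:

1. **Selective extraction.** White and black top-hats with a flat
   structuring element *B* extract bright and dark structures smaller than
   *B*, independently of the local background level. Both are computed in
   their rotational (RMP) form: the image is rotated clockwise through the
   N directions θᵢ = πi/N, opened (resp. closed) with *B*, rotated back,
   and the branches fused by pixelwise max (resp. min). The fusion keeps,
   at every pixel, the orientation in which the SE fits the local structure
   best, suppressing the SE-shaped artefacts of unidirectional filtering.
2. **Greyscale modification ν.** Each top-hat image is histogram-equalized
   (CDF remap over the display range) and then min–max stretched to the
   full display range. This lifts low-amplitude residues to a usable scale
   and homogenises the intensity inside each extracted target.
3. **Recombination.** λ(f) = f + ν(WTH′) − ν(BTH′), restricted to the
   display range.

All arithmetic is float64; integer pixel data are promoted on read and
quantized (round half away from zero, clip) only on write.

### Assumptions

- Targets are compact structures strictly smaller than the SE (the SE
  diameter must exceed the target base diameter, or the opening preserves
  the target and the top-hat misses it).
- The background varies smoothly at the SE scale, so it cancels in the
  top-hat differences.
- Images are single-channel; intensity is the only feature used.

## Parameters

| parameter | default | units | role |
|---|---|---|---|
| SE shape / size | disc, 31 | px (diameter) | scale/shape selectivity of the top-hats; set just above the largest target diameter |
| N (rotations) | 8 (disc/square), 36 (line) | — | isotropy of RMP; 1 = conventional morphology; gains saturate at the defaults |
| interpolation | bilinear | — | rotation resampling; `nearest` gives exact permutations at right angles on square frames |
| hist_bins | 256 | — | equalization resolution over the display range |
| out_min/out_max | 0 / 255 | grey levels | display range of λ's output |
| range_mode | clip | — | `clip` saturates out-of-range values; `rescale` min–max stretches instead |
| presmooth | off | — | RMP open-then-close with a disc-3 SE before enhancement, for noisy inputs |
| R_C, R_N (CIR) | 11, 41 | px (window side) | centre and neighbourhood windows of the local-contrast measurement |

## Numerical choices

- **Border rule.** Dilation/erosion (and image rotation) replicate edge
  values for out-of-frame samples. This keeps the operators extensive /
  anti-extensive at the frame and avoids spurious top-hat residues along
  the borders; the brute-force test oracles use the same rule.
- **Operator conventions.** Dilation is max over f(x−b), erosion min over
  f(x+b) (the adjunction pair), so opening = dilate∘erode and closing =
  erode∘dilate with the *same* SE are idempotent and correctly ordered for
  any SE, including asymmetric lines. For the symmetric disc/square
  defaults this coincides with the textbook symmetric forms.
- **Rotation.** Same-size rotation about the grid centre ((H−1)/2,
  (W−1)/2); corners that leave the frame are lost for that branch. Exact
  multiples of π/2 on square frames under nearest interpolation are
  executed as index permutations (`np.rot90`), making the right-angle
  algebraic identities exact rather than float-approximate.
- **Top-hat clamp.** Bilinear RMP branches can overshoot f by sub-quantum
  amounts; top-hat outputs are clamped at 0 so extracted-structure images
  are nonnegative, as their semantics require.
- **ν of a featureless top-hat is zero.** The equalization convention maps
  a constant image to display_max; applied to an all-zero top-hat this
  would inject a constant plane into λ. A constant top-hat therefore
  returns zeros, which also makes λ the exact identity on constant images.
- **λ range restriction = clipping.** Clipping preserves the absolute
  enhancement of mid-range structure; a `rescale` mode is provided for
  workflows that need the full output histogram. Equalization runs over
  the whole image including the zero background of top-hat images (no
  exclusion rule is applied).
- **Linear stretch divides before scaling** so the output extrema land
  exactly on the display bounds; constant images map to display_min.
- **CIR windows** are square, side R_C (centre) and R_N (neighbourhood),
  the annulus being their difference; the evaluation region defaults to
  the interior where the R_N window fits, and window means use float64
  sliding windows (agreeing with naive nested-loop sums to ≲1e-12).
  C is set to 0 where p + a = 0; a contrast-free *original* raises an
  explicit degenerate-input error rather than returning infinity.
- **CLAHE** is implemented directly (per-tile clipped histogram with the
  excess redistributed uniformly across bins, per-tile CDF lookup tables,
  bilinear blending between tile centres) so that its degenerate limit —
  one tile, clip limit too high to act — reduces *exactly* to the
  package's own global histogram equalization. The clip limit defaults to
  0.01 of the tile pixel count (floored at one count); edge tiles keep
  their true (smaller) pixel counts.
- **MSR** maps its raw log-domain response to the display range by the
  same min–max stretch used elsewhere in the package.

## The synthetic phantom

`generate_phantom` renders a 218 × 238 8-bit scene: base level 100, a
left-to-right linear ramp of 40 grey levels, optional low-frequency
sinusoidal modulation (off by default), six flat-disc targets of radius
10–13 px and amplitude 10–30 grey levels, and additive Gaussian noise with
σ = 2. Target diameters (21–27 px) stay below the default 31-px SE, the
regime the method is designed for; amplitudes stay below 12% of the
display range, so every local contrast value is under 0.15 — genuinely
low-contrast targets. The blob layout is fixed; the seed changes only the
noise realisation, so repeated runs are independent noise draws of the
same scene.

What the phantom does *not* emulate: anatomical texture, correlated
(quantum/structured) noise, scanner MTF blur, and targets with soft
Gaussian profiles or overlapping supports. Passing the pipeline's tests on
the phantom demonstrates the operator algebra, the metric, and the
relative behaviour of the three enhancement methods on compact
low-contrast targets over a smooth background — not clinical performance
on real radiographs.

## Design choices where the design was open

- The number of rotation directions is auto-selected from the SE shape
  (8/8/36) unless overridden; rotation interpolation is bilinear by
  default because nearest-neighbour rotation aliases strongly at
  non-right angles.
- Windowed CIR follows the |p−a|/(p+a), Σ(C−C̃)²/ΣC² form with square
  centre/neighbourhood windows of side 11/41; the formula is isolated in
  one function (`metrics.local_contrast_map` / `metrics.cir`) so an
  alternative convention is a one-function change.
- Even-sized disc/square SEs are rejected rather than silently recentred:
  an ambiguous origin would silently break the duality and idempotence
  guarantees.
- The evaluation pipeline (`scripts/acceptance.py`) uses the default
  phantom at full size; the morphology oracle checks run on 20×20 images,
  the CIR oracle on a 50×50 single-blob phantom — sizes at which the
  brute-force references stay fast while exercising every code path.

## Known limitations

- RMP branches at non-right angles involve interpolation, so exact
  algebraic identities (orderings, duality) are guaranteed only at N ∈
  {1, 2} with nearest interpolation; at bilinear defaults they hold to
  interpolation tolerance (and the top-hat clamp absorbs the residual).
- λ's ν-stretch amplifies *whatever* the top-hats extract; on noisy inputs
  without presmoothing that includes noise. This is inherent to the
  method, not a bug — hence the presmooth option.
- A pure-ramp image has zero windowed contrast everywhere (p = a for
  symmetric windows), so CIR is undefined on target-free smooth scenes;
  the metric raises a degenerate-input error there.
- Colour images, weighted (greyscale) SEs, 3-D morphology and DICOM I/O
  are out of scope.
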