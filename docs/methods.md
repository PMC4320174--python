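# Methods

## The enhancement model

The pipeline treats an underwater photograph as an 8-bit RGB image whose
histogram has been (a) shifted per channel by wavelength-dependent
absorption — red collapses toward zero, blue/green dominate — and
(b) compressed by veiling light. It corrects contrast in RGB space and
color in HSV space:

1. **Color balance (modified Von Kries).** Channel means R̄, Ḡ, B̄ are
   computed on the raw image; the median-mean channel is the reference and
   the other two are scaled by median/min (≥ 1) and median/max (≤ 1). Using
   the median rather than the dominant-cast channel keeps the largest gain
   moderate, which avoids the color falsification that a red-channel gain
   of 10–20× produces under a strong blue cast. Gains are applied once
   (no iteration) and the result is *not* clipped: clipping here would
   destroy the exact mean-equalization property, and the next stage
   renormalizes the range anyway. A channel with non-positive mean cannot
   be rescaled to a positive target and raises a degenerate-channel error.

2. **Global min-max stretch** maps each channel's observed [min, max]
   affinely onto [0, 255]. A constant channel is passed through with a
   warning rather than an error so flat inputs don't abort batch runs.

3. **Mean split + dual Rayleigh stretch.** The split point is the channel
   mean *recomputed after* the global stretch, so it reflects the
   renormalized histogram. Both region maps are applied to **all** pixels:
   the lower map sends [min, mean] onto [0, 255] and saturates everything
   above the mean at 255 (bright image); the upper map sends [mean, max]
   onto [0, 255] and saturates everything below the mean at 0 (dark
   image). Membership of the exact mean value is therefore immaterial.

   The Rayleigh target is realized as *histogram specification*: with
   u = clip((P − lo)/(hi − lo), 0, 1) and F the Rayleigh CDF at scale
   σ = α·255, the output is y = F⁻¹(u·F(255)) — the inverse CDF of a
   Rayleigh distribution truncated to [0, 255]. This map is monotonic,
   hits 0 and 255 exactly at u = 0 and u = 1, and makes a uniformly
   distributed region come out truncated-Rayleigh distributed (verified
   by a KS test at n = 100 000). A "literal" mode that instead evaluates
   the Rayleigh *density* at the affinely stretched value and rescales
   the result to [0, 255] is retained behind `mode="literal"` for
   comparison; it is non-monotonic (the density transfer rises then
   falls) and is not the default.

4. **Composition** is the plain per-pixel mean of the bright and dark
   images, computed in real arithmetic. Both derive from the same source,
   so no registration is involved.

5. **HSV correction.** The composed image is clipped/quantized to
   [0, 255], converted to HSV (hexcone model, via scikit-image), and the
   S and V planes are mapped by x ↦ clip((x − q₁)/(q₉₉ − q₁), 0, 1) where
   q₁, q₉₉ are the 1st/99th *percentiles of the data* (linear-interpolation
   definition). The alternative reading — fixed cuts at 1% of the value
   range — is not implemented. Hue is never modified. HSV (not HSI/HSL)
   is used; V is brightness.

Working precision is float64 throughout; quantization (clip to [0, 255],
round half away from zero) happens only at file output and before metric
computation, so rounding error does not compound across stages.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `alpha` | 0.4 | Rayleigh scale as a fraction of the 255 output range (σ = 102). No reference value is reported for this constant; 0.4 keeps the mode of the truncated distribution mid-range, matching the intended bell-shaped histogram. Configurable per run. |
| `mode` | `quantile` | `quantile` = truncated inverse-CDF specification (monotonic, default); `literal` = density-transfer variant for fidelity experiments. |
| `sv_percentiles` | (1, 99) | S/V stretch limits in percent of the data. |
| `skip_color_balance`, `skip_hsv` | off | ablation switches; the range/shape contract holds under any combination. |

## Quality metrics

Entropy is computed over k = 256 gray levels per channel and averaged
across channels by default (`per_channel_mean`); a `grayscale` mode first
collapses to luminance (0.299, 0.587, 0.114). Which variant the reported
comparison tables used is not stated, so both are exposed. MSE averages
squared differences over all pixels and channels. PSNR is implemented as
10·log₁₀(255²/MSE): the printed source formula (20·log₁₀ of peak/MSE
without a root) reproduces none of the reported reference rows, while the
standard form reproduces the arithmetically self-consistent rows to
±0.01 dB, so the printed formula is treated as a typo. Two reported rows
are internally inconsistent at that precision (one MSE printed as a
rounding of ≈201.5, one carrying a 1928→1982 digit transposition); the
test suite documents them and checks them at the precision their printed
values support. MSE = 0 reports a +infinity PSNR sentinel.

## The synthetic scene generator

`SceneSpec` defaults: 120×160 px, attenuation (0.25, 0.70, 0.85) —
fraction of signal retained per channel, red lowest; veiling light
(10, 130, 185) mixed at weight 0.35; contrast compression 0.55 about the
channel mean; Gaussian sensor noise with σ = 2 intensity levels. The clean
scene is a deterministic composite (illumination gradient, four textured
elliptical blobs with distinct hues, a bright sand band, one dark shadow)
drawn from `numpy.random.default_rng` with SeedSequence streams
[seed, 0] (scene) and [seed, 1] (noise), so pairs are reproducible
bitwise. The attenuation triple follows the typical shallow-water
signature in which the red channel retains the least signal; veil color
and weight were set so the degraded red mean sits well below 0.6× the
blue mean, the cast strength typical of the target imagery, and the
compression/noise levels so that degradation visibly costs entropy
(≈2 bits per channel) without burying the scene.

What the generator does **not** emulate: physically accurate radiative
transfer (no depth-dependent attenuation, forward/back scatter split, or
polarization), texture statistics of real coral, camera response curves,
or compression artifacts. Passing the suite therefore demonstrates that
the pipeline removes a gain+veil-type cast and restores range on scenes
with the right gross statistics — not performance parity on real reef
photographs.

## Numerical choices and degenerate inputs

- Rounding is half-away-from-zero (`floor(x + 0.5)` after clipping),
  the common imaging convention; stated because numpy's default differs.
- Rayleigh inverse CDF rejects u = 1 (infinite quantile); the pipeline
  always truncates the target, so u·F(255) < 1 by construction.
- Constant channels/planes pass through with warnings at every stage
  (global stretch, mean split, percentile stretch); errors are reserved
  for conditions the caller must fix (empty input, non-positive means,
  zero-width regions, shape mismatches).
- Channel-mean ties in the color balance are broken by (mean, R<G<B)
  ranking, which makes equal-means inputs exact fixed points.
- The ellipse rasterizer uses pixel-center inclusion; its pixel count
  tracks the analytic area πab to a few percent (the boundary term), and
  the test oracle is an independent per-pixel loop.

## Known limitations

- The literal Rayleigh transfer mode is kept only for comparison; its
  non-monotonicity reorders intensities by design.
- The bright/dark naming of the dual images follows their measured
  brightness (the lower-region map brightens); descriptions that label
  the lower-stretched image "under-enhanced" are reversed relative to
  this measurement, but the composition averages both images, so the
  final output is unaffected either way.
- Per-image values of the reported comparison tables cannot be
  reproduced because the 300 source photographs were never deposited;
  the synthetic suite substitutes directional checks (entropy gain,
  cast-ratio increase) at the same decision points.
- JPEG output is supported but lossy; byte-identity guarantees apply to
  PNG/TIFF/PPM.
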