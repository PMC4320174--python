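# uie — underwater image enhancement by dual-intensity Rayleigh stretching

Underwater photographs suffer a strong blue-green color cast (red light is
absorbed within the first few meters of water), a compressed dynamic range
from veiling light, and scenes that mix bright sand with dark shadow, so a
single global stretch under- or over-enhances one of the two. `uie`
implements an enhancement chain for 8-bit RGB underwater images built for
marine-imaging work (reef surveys, fish/coral photography) where objects
must be separable from the water background:

1. **Median-referenced Von Kries color balance.** With channel means
   R̄, Ḡ, B̄, the channel whose mean is the median is the reference; the
   minimum-mean channel is scaled by A = median/min and the maximum-mean
   channel by B = median/max, so all three means meet at the median and no
   gain is extreme.
2. **Global min-max stretch.** Each channel is mapped affinely,
   P_out = (P_in − i_min)(o_max − o_min)/(i_max − i_min) + o_min, onto
   [0, 255].
3. **Mean-split dual-region Rayleigh stretch.** Each stretched channel is
   split at its mean; the lower region [min, mean] and upper region
   [mean, max] are each mapped onto the full range so the output follows a
   Rayleigh distribution (CDF F(x) = 1 − exp(−x²/2σ²), σ = α·255, default
   α = 0.4) truncated to [0, 255], via the inverse-CDF quantile map
   y = F⁻¹(u·F(255)) with u the normalized position inside the region.
   This yields a bright image (lower map) and a dark image (upper map).
4. **Composition.** The two images are averaged pixel-wise, balancing
   under- and over-enhanced areas.
5. **HSV correction.** Saturation and value are stretched between their
   1st and 99th percentiles to [0, 1]; hue is untouched.

Quality is scored with discrete entropy H = −Σ p(x) log₂ p(x) over 256
gray levels, MSE, and PSNR = 10·log₁₀((2⁸−1)²/MSE) dB. A classic
per-channel histogram-equalization baseline and a seeded synthetic
underwater-scene generator (attenuation + veiling light + contrast
compression + sensor noise) are included, so the whole pipeline is testable
without external data.

## Worked example

```sh
uie synth --n 1 --seed 7 -o scenes/          # clean + degraded PNG pair
uie enhance scenes/scene_000_degraded.png -o enhanced.png
uie he scenes/scene_000_degraded.png -o he.png
uie metrics scenes/scene_000_degraded.png enhanced.png
```

On the seed-7 synthetic scene this prints (via `evaluate`):

```
degraded: entropy=4.901  means R/G/B = 27.4/113.6/146.5
enhanced: entropy=6.808 mse=6121.4 psnr=10.26 means R/G/B = 121.4/125.8/136.6
he:       entropy=4.884 mse=8318.8 psnr=8.93  means R/G/B = 135.6/131.9/131.3
```

The degraded input carries the underwater signature: the red mean (27.4)
is far below blue (146.5) and the per-channel entropy is low. Enhancement
raises entropy by ~1.9 bits (more usable gray levels, hence more visible
detail) and lifts the red/blue mean ratio from 0.19 to 0.89 (cast largely
removed), while the HE baseline equalizes brightness but gains no entropy
and incurs a larger deviation (MSE) from the input.

The same operations are available as a library:

```python
from uie import SceneSpec, make_scene, degrade, enhance, evaluate

spec = SceneSpec(seed=7)
clean = make_scene(spec)
degraded = degrade(clean, spec)
report = evaluate(degraded, enhance(degraded))
print(report.entropy, report.mse, report.psnr)
```

Other CLI entry points: `uie batch DIR --methods proposed,he -o report.csv`
for directory-level evaluation and `--save-stages DIR` on `enhance` to dump
every intermediate image. All flags can be mirrored in a `key=value` config
file (`--config`); flags win.

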