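# cemchron

Semi-automated counting of circum-annual growth increments in dental
cementum imaged with X-ray computed tomography.

Cementum, the mineralised tissue coating tooth roots, is deposited
appositionally throughout life in annual **increment pairs** — one thick
translucent plus one thin opaque layer per year. Counting these pairs
(cementochronology) estimates age at death in archaeology, forensic
science, wildlife biology and palaeontology, but manual counts on
histological thin sections are notoriously user-dependent. `cemchron`
implements an objective, statistics-driven counting workflow for greyscale
tomographic slice stacks, aimed at researchers who already have
high-resolution CT (or digitised thin-section) images of tooth roots:

1. **Straightening** — the circumferential cementum band of each slice is
   resampled along a user-drawn midline (natural cubic spline, unit
   arc-length steps, bilinear interpolation of ±*h* pixels along the local
   normals) into a rectangle whose rows run outer surface → cemento-dentine
   junction (CDJ) and whose increments run horizontally.
2. **Optional directional filtering** — a steerable first-derivative
   Gaussian filter, R(θ) = cos θ·(I∗G₀) + sin θ·(I∗G₉₀) with
   G₀ = ∂G/∂x, G₉₀ = ∂G/∂y, applied at θ = 90° to enhance the contrast of
   the horizontal increments.
3. **Image quality metrics** — SNR = ḡ_c/σ_b and
   CNR = (ḡ_c − ḡ_b)/√((σ_c² + σ_b²)/2) from paired 150×150 px cementum
   and background ROIs.
4. **Counting** — each slice is probed by 1000 random 10-pixel-wide radial
   transects. Per transect, the luminance profile is denoised with a cubic
   smoothing spline, a stiff baseline spline is subtracted (removing the
   radial density gradient), and the profile is split into five equal
   sections. In each section, events beyond cut-offs at mean ± ½·SD of the
   smoothed luminance are counted — at most one peak per above-mean
   excursion and one trough per below-mean excursion, merging events
   closer than 3 px (1.98 µm at 0.66 µm voxels). The transect pair count is
   min(#peaks, #troughs) plus recoveries of excursions truncated at
   section boundaries. Slice estimate = mean ± SD over transects; specimen
   estimate = mean over (typically 30) slices, rounded.
5. **Validation harness** — noisy sine patterns of known increment number
   (5–30) across signal-to-noise levels 0.9–0.1, 30 replicates per cell,
   flagged for accuracy (|mean − truth| ≤ 0.5) and robustness (SD < 1),
   plus 2D banded phantoms with gradients, band splitting and noise.

## Worked example

Counting three noisy synthetic slices of a 9-pair cementum phantom with a
radial density gradient:

```python
import numpy as np
from cemchron import (RunConfig, count_slice, count_specimen,
                      make_phantom, phantom_to_image)

cfg = RunConfig(n_transects=200, rng_seed=7)
rng = np.random.default_rng(cfg.rng_seed)
slices = []
for i in range(3):
    ph = make_phantom(9, width_px=120, height_px=400, gradient=True,
                      noise_sd=250.0, seed=10 + i)
    est = count_slice(phantom_to_image(ph), cfg, rng, label=f"slice{i}")
    slices.append(est)
    print(f"slice {i}: mean pairs {est.slice_mean:.2f}  SD {est.slice_sd:.2f}")
spec = count_specimen(slices)
print(f"specimen: mean {spec.specimen_mean:.2f} -> count {spec.specimen_count:.0f}")
```

prints

```
slice 0: mean pairs 9.00  SD 0.00
slice 1: mean pairs 9.00  SD 0.00
slice 2: mean pairs 9.00  SD 0.00
specimen: mean 9.00 -> count 9
```

Every transect of every slice recovered the 9 simulated annual pairs
despite the noise and the monotone density trend, so the slice SDs are 0
and the rounded specimen age estimate is 9 years (+ the age at which
cementum deposition began).

The same counting pipeline applied to one cell of the robustness sweep —
10-increment sine patterns at signal-to-noise 0.5, 30 replicates —
returns `mean 10.00, SD 0.00`: at that noise level the estimated count
matches the known count in every replicate.

There is also a CLI mirroring the library
(`cemchron straighten | filter | quality | count | validate | synth`,
with `--config cfg.yaml`, `--seed N`, `--out DIR`).

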