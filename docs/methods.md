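# Methods

## The counting model

Dental cementum grows by apposition: each year adds one translucent
(dense, bright in phase-contrast CT) and one opaque (darker) layer. Along
a radial line from the outer cementum surface to the cemento-dentine
junction (CDJ), the greyscale profile is therefore modelled as a
roughly periodic oscillation — one peak-trough system per annual pair —
superimposed on (a) an overarching monotone density gradient rising
towards the CDJ, and (b) pixel noise. The counting problem is to estimate
the number of oscillation periods per radial profile, robustly against
both confounds, without a human deciding which wiggles are "real".

Three statistical devices carry the method:

* **Local statistics.** Each transect is split into `n_sections = 5`
  equal sections, and peaks/troughs are referenced to the *section's* mean
  and SD rather than the whole transect's. Without this, the density
  gradient puts the outermost genuine peaks below the global mean and the
  innermost genuine troughs above it, and both are lost.
* **Cut-offs.** An extremum is counted only if it departs from the section
  mean by more than `cutoff_factor = 0.5` standard deviations of the
  smoothed section. This is the core defence against noise wiggles.
* **Rejection rules.** (i) At most one candidate peak per above-mean
  excursion (the largest; secondary maxima riding on the limbs of a
  genuine peak — accessory increments or noise — share its excursion and
  are rejected). (ii) Counted events closer than `min_separation_px = 3`
  pixels (1.98 µm at the default 0.66 µm voxel size) are merged, keeping
  the larger excess; ties keep the earlier event. (iii) The pair count is
  min(#peaks, #troughs): only one peak is counted for every trough.

Why excursion-level uniqueness rather than strictly alternating counted
events: a strict-alternation merge deletes a *genuine* peak whenever the
trough between two peaks narrowly misses its cut-off, losing two events
for one noisy miss. Measured on the validation sweep this inflates the
count bias several-fold. Two counted peaks separated by a below-mean dip
were never piggy-back features in the first place — the signal returned
below the mean between them — so the rejection is applied within
excursions only.

## Smoothing and baseline removal

Noise is suppressed with a cubic smoothing spline before any statistics
are computed. Two deliberate choices:

* **One fit per transect, not per section.** At the smoothing strengths
  the noise levels demand, the equivalent kernel is comparable to a
  section's length; fitting sections independently flattens extrema near
  section edges (a clean 6-cycle profile loses 4 of its 6 counts).
  The spline is fitted to the whole tissue extent and *evaluated* per
  section; section statistics remain local.
* **Spectral penalty selection.** The spline penalty λ is chosen per
  transect from the profile's dominant luminance frequency f₀ (argmax of
  the linearly detrended periodogram, searched up to 1/(2·min_separation)
  = 1/6 cycles/px — oscillations faster than the separation rule cannot be
  genuine increments). The denoising spline has half gain at
  `smooth_cutoff_factor · f₀` (default 1.25); a much stiffer baseline
  spline with half gain at `baseline_cutoff_factor · f₀` (default 0.75)
  is subtracted, removing the density gradient and low-frequency noise
  while passing the increment oscillation. Generalized cross-validation —
  the textbook alternative, and the default of the standalone
  `smooth_section` operation — was rejected for the pipeline: it targets
  mean-squared error, not counting error, and under heavy noise leaves
  pass-band noise that both creates and destroys extrema (biases of −3 to
  +9 counts across the validation sweep), besides being ~60× slower.
  An explicit `smooth_lambda` override disables the spectral selection.

Implementation: on the unit-spaced grid the cubic smoothing spline is the
second-difference-penalized least-squares smoother, diagonal in the DCT
basis (gain 1/(1 + λ(2 − 2cos ω)²)); the denoising fit uses this O(n log n)
form. The baseline fit instead uses a B-spline smoother with natural
boundary conditions (λ = (2πf_b)⁻⁴), because the DCT's implicit even
reflection forces zero slope at the profile ends and biases the baseline
wherever the tissue edge sits away from the local mean — enough to lose
the first or last increment of a clean profile.

Peak detection is plateau-aware: profiles sampled symmetrically around an
extremum produce two-sample plateaus that strict neighbour comparisons
miss; the plateau's centre index is taken as the extremum.

## Section boundaries

Sections are contiguous, lengths differing by at most one pixel, the
remainder assigned to the innermost (CDJ-side) sections where the oldest,
thinnest increments lie. An excursion whose apex/nadir falls exactly on a
section edge is counted by the **boundary pass**: for each internal
boundary, the terminal limb of the left section (beyond its last counted
event) and the initial limb of the right section are concatenated; if
they form an interior excursion crossing the upper cut-off of one
flanking section and the lower cut-off of the other, with both limb bases
on the far side of their sections' means, one pair is added (at most one
per boundary). Pairing is transect-global — min over the merged, ordered
event list — because partial periods at section boundaries make summed
per-section pairing undercount (a clean 7-cycle profile over 5 sections
would count 5).

## Transect sampling, screening and aggregation

`n_transects = 1000` vertical 10-px bands per slice are drawn uniformly
with replacement (narrow phantoms can have fewer distinct positions than
transects); each band's per-row mean forms the profile, and its tissue
extent is the span of non-zero values (straightening writes background as
exactly 0). Transects shorter than mean − 1·SD of the *original* sample's
lengths are redrawn until compliant (cap: 100·n draws) — these clip
regions where the midline annotation captured too little cementum. Slice
estimate: mean ± SD of all transect counts. Specimen estimate: mean of
(typically 30) slice means, rounded to the nearest integer by default or
to the nearest 0.25 in `"quarter"` mode; half-way ties round away from
zero. All randomness flows from one seeded `numpy` generator; fixed seed
and inputs reproduce every report bit for bit.

## Straightening and filtering

The midline is interpolated with a natural cubic spline through the
user's control points, re-parameterised to unit arc length; profiles of
2h+1 bilinear samples are taken along local normals, oriented so row 0
faces away from the image centre (outer surface first). One midline is
propagated across as many slices as it fits, with per-slice coverage
logged so the user knows where to re-annotate — midline placement remains
the semi-automated, human step of the workflow.

The steerable filter uses the first-derivative Gaussian basis
(σ default 2 px, smaller than the thinnest expected increment ≈ 3 px at
0.66 µm voxels, to avoid merging bands; kernel radius ⌈3σ⌉). The raw
response is signed; for storage and for counting, `filter_straightened`
re-maps tissue responses to the positive bit range and zeroes everything
within one kernel radius of the background, where the tissue/air step
dominates the derivative. Counting statistics are relative, so affine
rescaling — and bit depth generally — cannot change counts.

## The synthetic validation suite

`make_sine` emulates a transect profile with `true_count` full sine
periods over `length_px = 1000` samples (comparable to a real transect at
sub-micron voxels), amplitude 100, plus white Gaussian noise, offset to
keep values positive. The **snr parameter is interpreted as the signal's
share of total variance**: noise SD = (A/√2)·√(1/snr − 1). The
alternative amplitude ratio (noise SD = A/snr) is available as
`noise_model="amplitude_ratio"`. The variance-fraction default was chosen
because it is a normalised quantity consistent with a 0.1–0.9 scale and
because the counting algorithm's measured behaviour under it spans the
full qualitative range a validation sweep should probe — essentially
exact recovery at snr ≥ 0.5 (noise SD up to ≈ 0.7·A), graceful
degradation at 0.4–0.2, and count errors with SDs approaching 1 at 0.1
(noise SD ≈ 2.1·A) — whereas under the amplitude ratio even the mildest
level (0.9) puts the noise SD above the signal amplitude and per-cycle
counting information vanishes at every tested level.

`make_phantom` emulates a straightened slice: horizontal band pairs with
a sinusoidal radial profile that starts and ends at mid-grey (so all
n_pairs maxima and minima are interior and countable), an optional linear
gradient rising towards the CDJ, optional band splitting (a Gaussian dip
splits a light band into two maxima over a column range, emulating an
accessory increment), additive noise, and a 1-px zero margin delimiting
the tissue.

`robustness_sweep` runs `count_transect` on 30 replicates per
(count 5–30) × (snr 0.9–0.1) cell; per-cell seeds derive from the master
seed via `SeedSequence`, so any cell is reproducible in isolation. Cells
are flagged accurate if |mean − truth| ≤ 0.5 and robust if SD < 1.

## Problem sizes and determinism in the shipped checks

The test suite exercises slice-level operations at 20–200 transects per
slice and phantom widths of 60–120 px; the validation-facing tests and
`scripts/acceptance.py` run the sweep at full size for snr ≥ 0.5
(26 × 5 × 30 = 3900 patterns, ≈ half a minute) and at 26 × 3 × 30 for
snr 0.4–0.2. All stochastic tests fix seeds; hypothesis-based property
tests run derandomised.

## Known limitations

* The midline is user input; no automatic cementum segmentation is
  attempted, and coverage logging is only a heuristic for when to
  re-annotate.
* Increments within roughly half a period of the tissue edges are
  under-detected (edge extrema are not countable, and even the
  natural-boundary baseline is least constrained there). The phantom
  generator's mid-grey edge phase avoids this by construction; real
  profiles whose outermost increment hugs the surface may lose it.
* A 90°-oriented derivative response shifts extrema by a quarter period;
  where that pushes an edge extremum out of the tissue, counts on
  filtered images can differ by one from counts on unfiltered ones.
* The sine suite probes white Gaussian noise only; structured noise
  (reconstruction artefacts, cracks), increment splitting/coalescence
  beyond the phantom's simple split model, and cellular-cementum regions
  are not emulated, so passing the sweep does not certify performance on
  pathological real tissue.
* The dominant-frequency selection assumes one dominant periodicity per
  transect; profiles mixing two strong periodicities (e.g. heavy accessory
  layering) will be smoothed for whichever dominates the periodogram.
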