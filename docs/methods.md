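# Methods

## The measurement model

A swept-source OCT B-scan is an 8-bit grayscale matrix: rows are depth
(axial pitch 0.024445 mm/row, 448 rows ≈ 10.95 mm), columns are lateral
position (default 512 columns over 5 mm). Tissue back-scatter decays
approximately exponentially with depth, and the decay rate — the optical
attenuation coefficient — discriminates glioma (≈ 4.8) from peritumoral
brain (≈ 6.4) on the scale used throughout this package.

The per-column two-point estimator is

    mu_t = (10 / L) * log10(P_i / P_L),    L = n_rows × 0.024445 mm.

Estimates > 11 (strong-reflection start point or low-gray end point) or
< 0 (end brighter than start) are discarded; accepted values therefore
lie in [0, 11]. The formula yields dB/mm; the published tissue tables
label the same numbers mm⁻¹ without applying the ≈ 4.34 conversion
factor between the two scales. The package follows the formula
numerically and performs no conversion, so its outputs are directly
comparable to those tables.

### Start and end rules

* **Start** (`fourth_largest`, default): sort the column, take the
  fourth-largest gray value; the starting row is the earliest row
  attaining it (ties break toward the probe). This tolerates up to three
  specular spikes. A plain `max` rule is available for single-specimen
  measurement.
* **End** (`running_mean_lt_45`, default): slide a five-pixel window one
  row at a time below the start; stop at the first window whose mean is
  below 45. `P_L` is that window mean. The *ending row is the window
  centre* (first index + 2): the window mean is an estimate of the
  signal at the centre, and anchoring `L` at the window's first row
  would systematically shorten the segment by two rows — a provable
  +3.5 % bias at mu ≈ 4.6 and +5.5 % at mu ≈ 6.4 on exact exponential
  profiles. Windows truncated by the image bottom are not evaluated.
  The alternative `band_40_80` rule (first pixel whose gray lies in
  [40, 80]) reproduces the single-specimen measurement convention.
* Columns whose start value does not rise above the end criterion
  (blank or all-background A-lines) yield `no_segment` rather than a
  spurious near-zero estimate; so do columns that never decay below the
  criterion (saturation).

### Derived metrics

* **Trendline**: the depth profile (single A-line or column-band mean)
  averaged every 10 rows; trailing partial blocks use their actual
  length; peak ties break toward the shallow side. The descending-angle
  metric measures the angle between the descending segment and the
  vertical (gray) axis after normalizing the plot to a 4:3 box (full
  block axis → 4 units, full gray range → 3 units):
  `angle = atan(dx'/dy')`. The segment runs from the peak to the first
  post-peak block below 45 (the estimator's stop level, chosen for
  consistency; the original interactive measurement never specified an
  endpoint), falling back to the post-peak minimum (recorded in
  `descent_rule`). Gentle decay ⇒ large angle, so gliomas score larger
  angles than peritumoral brain; a flat segment returns 90° and is
  flagged.
* **Grid statistics**: pixel counts in inclusive gray bands over fixed
  ROIs (defaults 55×100 with bands 70–140 / 70–110 ex vivo, 55×80 with
  100–140 in vivo). Inclusive endpoints match interactive threshold
  semantics. Automatic placement sets the ROI top at the median
  per-column surface index ("midline of the top layer" is not precisely
  defined anywhere, so placement is explicit and logged).
* **Surface extraction**: binarize at gray > 70 (strict, used uniformly
  for surface and side faces), one morphological opening then closing
  with a 3×3 square (the named operations come without a kernel spec;
  3×3/one iteration is the minimal choice and is recorded in output
  metadata), then the first foreground row per column. Border-replicating
  morphology keeps edge columns intact.
* **Interleaving**: P bidirectional passes of N slices each are woven
  position-major (slice i of pass p at output index iP + p) after
  reversing backward passes, dividing the slice spacing by P (ten passes:
  0.187 → 0.0187 mm). The permutation is recorded and exactly
  invertible. Because the source descriptions of the raster (pass
  counts, 215 images, step sizes) are mutually inconsistent, pass count
  and base spacing are explicit inputs, never guessed.
* **Color classification**: red [0, 5), yellow [5, 6), green [6, 11],
  white otherwise/undefined. Half-open boundaries make edge ownership
  deterministic (5 → yellow, 6 and 11 → green). Ramps interpolate
  (96,0,0)→(255,0,0) and (0,96,0)→(0,255,0); only the ramp *direction*
  (darker near the zone floor) is prescribed by the display convention,
  the RGB endpoints are this package's choice.
* **Statistics**: Welch's unequal-variance t-test (group SDs differ up
  to five-fold between tissue classes, making the pooled test
  inappropriate; the original analysis names no test family, and the
  choice is recorded in every report). ROC/AUC via the Mann–Whitney
  pairwise identity with half-weight ties; the classifier direction is
  an explicit parameter with auto-detection (attenuation:
  lower-is-tumor). No multiple-comparison correction is applied, and
  specimens are treated as independent observations. Sample SDs use the
  n−1 denominator.

## The phantom

The generator is the statistical inverse of the estimator. Below a
surface row placed at the drawn probe standoff, the noise-free gray is

    I(z) = surface_intensity × 10^(−mu_true · z / 10),

so the estimator recovers `mu_true` up to quantization (the noise-free
round trip over mu ∈ 1…10 is accurate to < 0.05). Rows above the surface
sit at a background level (default 20).

**Presets.** Each tissue class ships its published across-specimen
statistics: attenuation mean ± SD (e.g. grade-4 tumor 4.62 ± 0.98,
combined glioma 4.81 ± 1.51, combined peritumoral 6.40 ± 0.53, all drawn
truncated to (0, 11)) and probe standoff as a truncated normal (glioma
scans 2.22 ± 0.89 mm on [0.4, 4.6]; peritumoral 2.08 ± 0.86 mm on
[0.7, 4.0]). Attenuation varies at the *specimen* level — one draw per
specimen, shared by its columns — because the published SDs are
across-specimen. Surface intensities (124 tumor, 164 peritumoral) were
set so the first full-tissue trendline block reproduces the observed
profile peaks (≈ 110 vs ≈ 140 gray) at the preset mean attenuation.

**Noise.** Speckle is a multiplicative mean-one gamma field (shape
k = 100) smoothed over the effective resolution cell (Gaussian, σ = 2
rows × 1 column), plus additive Gaussian background noise (SD 2 gray
levels), then clipping to [0, 255] and 8-bit quantization. The noise
level emulates the *display-processed* B-scans the measurement chain
actually ingests (acquisition-time averaging plus rendering), not raw
fully-developed speckle: the contrast was calibrated once so that the
two-point estimator is unbiased (|bias| < 0.01) against generator truth
for the anchored presets. Raw-speckle texture (k ≈ 1–4, per-pixel) is
available through the preset's `speckle_shape` field, but note that the
fourth-largest start rule and the first-passage stop rule are *not*
unbiased under heavy per-pixel noise (k = 4 inflates estimates by
≈ +1 dB/mm) — a property of the published estimator itself, not of this
implementation.

**Scenes.** B-scans share one standoff draw plus a smooth random surface
height field (Gaussian-smoothed white noise, 0.5 mm correlation length,
default 0.05 mm SD) emulating undulating specimen topography. Scenes
support lateral region partitions (tumor | normal boundaries), and thin
bright inclusions (< 3 mm deep, nerve/epineurium-like). Multi-pass
acquisitions reuse one specimen truth per position with fresh noise per
pass, so repeated slices differ only minutely; odd passes are stored in
reversed spatial order with position labels preserved.

**What the phantom does *not* model:** interferometric wave optics
(dispersion, sensitivity roll-off, shadowing), OCT-angiography or
elastography contrast, lateral PSF blur, refraction at the surface, and
real histological heterogeneity within a specimen. Passing tests
therefore demonstrate the correctness and calibration of the
*measurement chain*, not clinical performance on human tissue; the
published real-data AUCs, angles, and pixel counts come from unpublished
per-specimen data and are used only as directional anchors.

## Problem sizes and seeds

All randomness flows from `numpy.random.SeedSequence`, so every run is
bit-reproducible under a fixed seed. The shipped study sizes are the
published ones where known (60 vs 21 specimens for group comparisons; 60
scans for standoff recovery) and otherwise chosen for tight sampling
error at interactive runtimes: cohort-mean round-trip checks use 500
specimens per preset (standard error ≈ 0.07 for the widest preset), and
the Welch power check repeats 100 seeded cohort draws. The acceptance
script reports each quantity with the size used.

## Known limitations

* The 8-bit image path quantizes gray values; estimates from short
  segments (high mu, dim surfaces) carry quantization noise of a few
  hundredths dB/mm.
* `estimate_column` requires the surface to be in frame; standoffs
  beyond the imaging depth raise rather than extrapolate.
* The descending-angle endpoint convention (< 45) is a package choice;
  angles are comparable within this package but not necessarily to
  interactive measurements with a different endpoint.
* ROC confidence intervals are not computed; the reported AUC is the
  point estimate.
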