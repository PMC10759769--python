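# Methods

This note documents the models behind `kiwifuse`: what the synthetic study
generator emulates, how each analysis stage is defined, the parameters that
matter, and the choices made where the design was genuinely open.

## The synthetic study

The generator produces labeled fruit for three growing regions — Talesh,
Langarud and Rasht (integer codes 1, 2, 3) — each sample consisting of a
whole-fruit RGB image, a middle-cut RGB image with exact ground-truth
tissue masks, thirteen gas-sensor voltage curves, and a physicochemical
record. Two dials control the study difficulty:

* `separation` ∈ [0, ∞): scales every between-region difference. At 1 the
  physicochemical means equal the published regional means (e.g. Langarud
  SSC 20.96 °Brix, Rasht firmness 1.20 kg/cm², Talesh pH 3.83); at 0 all
  regions collapse onto the grand mean.
* `noise_scale` ∈ [0, ∞): scales all within-region variability —
  physicochemical coefficients of variation (base CV 0.05 per attribute),
  pixel noise (sd 2.5 at scale 1), per-fruit pigment jitter, sensor noise
  and drift. At 0 every curve and image is exactly its closed form, which
  the identity tests exploit.

### Physicochemical records

Each of twelve attributes is drawn from a truncated normal with the profile
mean and sd = mean × CV × noise_scale, bounded below at 10% of the mean
(pH additionally capped at 7). BAR is never sampled: it is recomputed as
SSC/TA after sampling, so the quotient identity holds exactly for every
record. The published per-region BAR values are therefore not generative
inputs; the generator's full-separation BAR means are the quotients of the
SSC and TA means (e.g. 20.96/0.55 = 38.11 for Langarud).

### Images

Scenes are concentric ellipses on a uniform background, 1600×1600 px by
default (a 2000 px option exercises the center-crop; smaller sizes scale
the geometry proportionally for fast tests). The default cut geometry uses
fruit semi-axes (520, 470) px, a locule outer bound at 0.52 of the fruit
axes, and core semi-axes (118, 96) px; per-sample shape jitter is ±4% per
axis. The cut face fills the fruit ellipse edge-to-edge: at this resolution
the ~1 mm skin rim of a real equatorial cut is sub-pixel, so no skin
annulus is painted on the cut (the skin color is used for the whole-fruit
render only).

Colors are chosen so the segmentation contrasts are structural, not
incidental: outer pericarp (150, 200, 60) has ExG = +190, core
(235, 225, 205) ExG = +10, locule (200, 40, 60) ExG = −180, with radial
streak texture in the locule; the margins between tissue ExG distributions
exceed 4× the ExG noise sd at any plausible noise level. The background is
a faintly cool white (238, 243, 250) rather than a neutral white: the hue
of an achromatic pixel is numerically unstable under noise, and the tint
pins the background hue far from the fruit hues that the hue-channel
threshold separates.

Region identity expresses itself visually through pigmentation:

* locule shifts (at separation 1): Talesh (+5, +16, −14) toward orange-red,
  Langarud (+22, −12, −6) toward deep red, Rasht (−18, +10, +10) toward
  pink. The three vectors are deliberately non-collinear — regions differ
  in pigment composition, not merely in the amount of one pigment — so no
  region sits "between" the other two in color space.
* weaker non-collinear shifts (≈5–7 units) on skin, outer pericarp and
  core: surface and flesh tints also track the growing climate, but far
  more weakly, which is why whole-fruit appearance alone is a poor
  region discriminator while the cut face is a good one.
* per-fruit variability: pigment jitter per tissue (sd 2.5–3 ×
  noise_scale) plus a common illumination gain (sd 1.5% × noise_scale).
  Without per-fruit color variation, tissue color means would be
  near-constant across samples and standardization would amplify them into
  pure-noise directions of the PCA.

### E-nose curves

Thirteen channels (8 MQ + 5 TGS ids by default; the labels are
configurable) on a 1 Hz grid t = 1..220 s. Per sensor s with baseline
voltage V0_s (1.1–2.0 V), rise time constant τ_s (5–8.5 s) and recovery
constant (17–22.5 s):

* baseline (t ≤ 120 s): V0_s plus a linear drift (slope ≤ 0.2% of V0 ×
  noise_scale) and Gaussian noise (sd 0.4% of V0 × noise_scale);
* injection (120 < t ≤ 160 s): V0_s (1 + A_s (1 − exp(−(t−120)/τ_s)));
* recovery (t > 160 s): exponential return toward V0_s from the t = 160
  value.

The amplitude couples aroma to quality: A_s = gain_s (1 + κ·z) with
κ = 0.3 and z the sample's standardized SSC ((SSC − 19.0)/1.5 °Brix).
SSC is the single latent linking the two modalities; this keeps the SVR
parameter-recovery question well-posed: a pipeline that recovers SSC from
aroma features demonstrably preserves the latent through normalization,
MSR extraction and PCA. Region gains interpolate with `separation` and
keep Langarud's gain highest on every channel, reproducing the radar-plot
ordering in which Langarud fruit emit the most volatiles.

### What the generator does not emulate

Photorealistic fruit texture, illumination gradients and shadows, camera
optics, sensor drift chemistry, humidity/temperature effects, and headspace
equilibration kinetics. Consequently, passing tests show that the analysis
pipeline is correct and statistically well-behaved under the stated
generative assumptions — not that it would reach the same accuracies on
real orchard data, where segmentation and within-region variability are
much harsher.

## Image analysis

Processing order is crop → segment → measure. The center crop defaults to
1600 px (shrunk to the image when smaller). Whole-fruit segmentation is
grayscale Otsu (fruit darker than background), opening with a disk of
radius 5 px at 1600 px scale (scaled proportionally at other sizes),
largest connected component, hole filling. Opening is implemented in its
standard form (erosion then dilation), the operation that removes small
bright/dark specks — the noise-removal role it plays here; the reversed
composition would be closing, a different operation.

Middle-cut segmentation: (1) Otsu on the hue channel rotated by 0.5 so red
and near-zero hues form one mode, taking the more saturated side as fruit;
(2) the same morphological cleanup; (3) within the section, two-threshold
multi-Otsu on ExG, highest class → outer pericarp; (4) Otsu split of the
remainder, the class with mean ExG nearest zero → core (cleaned by opening
+ largest component); (5) locule = section − outer − core, so the partition
invariant holds by construction. Whether the original two-region ExG
thresholding used one or two passes is not stated anywhere; the two-stage
scheme is one consistent reading and is validated against generator truth
(IoU ≥ 0.95/0.90). A region smaller than 0.5% of the section, or a locule
residue that loses more than half its pixels under opening (salt-and-pepper
rather than a ring), raises a segmentation failure naming the region.

Morphology: area is the pixel count; roundness is 4πA/P² with the
perimeter measured as the polyline length of the outer boundary contour
subsampled every 5th vertex — a raw digital contour overestimates a
circle's perimeter by ~5% (roundness 0.90 for a perfect disk), while the
subsampled estimate gives 0.99 for a disk and π/4 + 0.004 for a square;
aspect ratio is the moment-equivalent ellipse axis ratio. Color means are
taken over mask pixels only: RGB on [0, 255], HSV from the standard
hexcone conversion on [0, 1], CIELAB via sRGB → CIEXYZ (D65) → CIELAB.
Channel scales are fixed conventions of this package since no standard
exists across toolboxes.

## E-nose analysis

The baseline Xs(0) is estimated as the mean raw response over the last
10 s of the baseline phase (t ∈ [110, 120], configurable) rather than the
literal first sample: robust to noise, identical to the raw baseline in
the noiseless limit. Normalization is the fractional change
Ys(t) = (Xs(t) − Xs(0))/Xs(0), which is exactly invariant to any positive
gain applied to the raw curve. The MSR is the maximum of Ys over
t ∈ [121, 140], both endpoints inclusive (exactly 20 samples at 1 Hz); for
a noiseless curve it equals the closed form A_s (1 − exp(−20/τ_s)). No
smoothing is applied before the maximum. A non-positive baseline estimate
raises an invalid-signal error.

## Modeling

Fusion is feature-level: the 46 visual features followed by the 13 MSR
features, one 59-vector per fruit, fused before any reduction. The split
is stratified 2/3 calibration / 1/3 test with the test share rounded up
per class; all standardization and PCA statistics come from calibration
data only (asserted by tests). PCA operates on z-scored features
(correlation structure) because pixel areas and MSR fractions differ by
orders of magnitude; constant features are dropped with a warning. Four
components are kept by default (configurable; score plots of e-nose-only
data are essentially 2-dimensional, but four PCs are fed to the models
throughout for a uniform protocol).

SVM and SVR use the degree-2 polynomial kernel (γ·x·y + 1)², one-vs-one
voting for the three classes, and the 5 × 5 grid c, γ ∈
{0.01, 0.1, 1, 10, 100}. Selection minimizes 10-fold CV RMSE — on integer
region codes (1, 2, 3) for classification, since a numeric RMSE is
reported for classifiers and the encoding must be fixed somewhere — with
ties resolved to the first pair in row-major grid order. CV folds are
stratified for classification and plain shuffled for regression, both
seeded. "Validation" metrics are computed from the pooled out-of-fold
predictions of the winning pair; "test" metrics from the untouched third.
SVR targets are z-scored internally with calibration statistics (the
ε-insensitive tube, ε = 0.05, is scale-dependent and targets span three
orders of magnitude) and predictions are back-transformed. libsvm's SMO
solver can stall indefinitely on degenerate grid extremes (near-constant
kernels at γ = 0.01, exploding ones at γ = 100), so fits are capped at
20 000 iterations; capped fits simply lose the grid search.

Metrics: accuracy = 100 × correct/total; RMSE = root mean squared
residual; R² = 100 × (1 − SSres/SStot). Degenerate inputs (length
mismatch, constant truth, single class, constant target) raise errors
rather than returning NaN.

## Experiment orchestration and problem sizes

`run_experiment` is deterministic from its seed (dataset seed, split seed,
fold seeds all derive from the config) and reruns byte-identically. The
default targets are region plus the ten modeled quality indices; free
sugars are generated but not modeled by default. Feature-set rankings sort
by the validation metric, ties keeping the fixed order e-nose < image <
fused.

Reference study conditions are 15 fruit per region, separation 1.0 and
noise scale 0.3 at 1600 px — the configuration the acceptance script
reruns. Multi-replicate statistical checks (fusion dominance across ten
seeds at moderate noise 0.5, separation monotonicity, segmentation scored
over 20 scenes at the default noise 1.0) run on 512 px or 256 px scenes
with proportionally scaled geometry; segmentation quality is scale-stable
(worst-case IoU 0.997 at 512 px), so the smaller scenes measure the same
behavior at a fraction of the rendering cost. "Moderate noise" for the
dominance check is 0.5, the same regime in which SVR latent recovery is
specified; at noise 1.0 the SSC latent's within-region spread overlaps the
regional separation and the e-nose modality itself degrades.

## Known limitations

* The generator's within-region covariance is diagonal per attribute
  (plus the shared SSC latent); real fruit quality attributes co-vary.
* Hue means are arithmetic, not circular; with the palette used, tissue
  hues never straddle the wrap point far enough for this to matter, but
  extreme custom palettes could bias the locule hue mean.
* The classifiers' reported RMSE on integer class codes depends on the
  arbitrary region ordering; it is kept for protocol fidelity, while
  accuracy is the meaningful classification metric.
* The reference conditions emulate a 45-fruit field sample. Accuracies
  from samples this small carry wide confidence intervals; the synthetic
  results characterize the protocol's behavior under the stated generative
  assumptions, not the performance attainable on any particular orchard
  dataset.
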