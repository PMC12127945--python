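# Methods

`cxrqc` is a staged quality-control (QC) chain for chest radiographs plus
the dataset-level machinery (curation, evaluation, shortcut analysis) that
a model-development workflow needs around it. This note records the models
and procedures each stage implements, the defaults and why they hold, what
the synthetic phantom generator does and does not emulate, and the design
choices that were genuinely open.

## Canonical image representation

Ingest (`dicom_io`) maps every file to a float64 matrix in [0, 1], scaled
over the *stored* value range (2^bits − 1), not the observed range, so
digital padding at stored value 0 remains exactly 0. MONOCHROME1 data are
inverted at the door; downstream, higher intensity always means more
radiodense (bone bright, air dark). Missing header fields become `None`,
never 0 — curation must distinguish an absent deviation index from a zero
one. Decode failures are not exceptions: they yield a record carrying a
single `exclude` verdict (reason `decode_error`) so one corrupt file
cannot halt a batch.

## Stage 1 — intensity standardization

`apply_windowing` is a linear value-of-interest (VOI) map: values at or
below `center − width/2` go to 0, at or above `center + width/2` to 1,
linear in between. The stage uses the header window when the file carries
one and otherwise falls back to an auto-window spanning the 1st–99th
percentiles of the non-zero pixels (padding is excluded so it stays
black).

The two paths have different characters, and the distinction matters for
the harmonization statistics (per-image coefficient of variation, SD, and
256-bin Shannon entropy; standardized mean difference between
manufacturer groups, SMD = |Δmean| / √((s₁² + s₂²)/2) with sample SDs):

* A *header* window is a vendor display calibration. When vendors apply
  roughly affine intensity transforms with distinct gains and offsets,
  their windows map each vendor's output span onto a common display band,
  which compresses over-contrasted data (mean CV, SD and entropy all
  fall) and removes the between-vendor location/scale difference (SMD
  falls for all three statistics). This is the behavior the acceptance
  suite verifies on a two-vendor synthetic cohort.
* The *auto-window* is a percentile stretch. A stretch cannot reduce the
  SD of data already normalized to [0, 1] — the map fixes the percentile
  span onto the full interval, so its slope is ≥ 1 and only ~2% of mass
  is clipped. It exists as a fallback for files with no window header; it
  standardizes range, not dispersion.

Harmonization statistics are meaningful on the exposed field. Padding and
collimation pixels map to vendor-dependent display values (window offsets
differ) and would contaminate whole-image statistics; measurements of
harmonization in the tests therefore use cohorts without borders, while
the pipeline computes the per-image statistics as informational evidence
either way.

## Stage 2 — geometry

**Border cropping** runs two peeling passes from the image edge inward,
capped at 45% removal per dimension (a safety bound: aggressive cropping
is worse than residual border):

1. *Padding*: border lines that are exact-constant within `pad_tol`
   (default 1/1024 of the intensity scale).
2. *Collimation*: border lines whose mean falls below an absolute
   near-black threshold on the stored scale (`collim_threshold`, default
   0.04). Unexposed collimator shadow is near-black regardless of the
   anatomy; content-relative cutoffs (low quantiles, median fractions)
   were tried first and fail in both directions — with a wide band the
   low quantile falls *inside* the band's own distribution, and with dark
   content the band's line means straddle a median-relative cutoff.

The pipeline detects borders on the pre-window (stored-value) image and
applies the crop to the standardized image: vendor display windows
compress dark contrast and can push collimation and free-air intensities
together after windowing. An image whose remaining content is itself
constant or near-black is excluded as `empty_content`.

**Rotation correction** scores each 90° candidate with an
upright-orientation score: bottom-minus-top mean intensity (the
radiodense abdomen/diaphragm sits at the bottom of an upright film in the
canonical polarity) plus 0.5 × vertical-mirror symmetry (high for frontal
films, low when rotated sideways), computed on a 64×64 anti-aliased
downsample. Ties prefer 0°, then 90°, 180°, 270°. This is a heuristic:
it recovers ≥ 95% of synthetic rotations and misclassifies mainly
heavily atypical laterals.

**Aspect screening** flags images whose width/height ratio (ncols/nrows;
the convention is fixed here and used consistently) falls outside
inclusive bounds, default 0.85–1.48 — the published optimum for this
family of QC tools — overridable in configuration.

## Stage 3 — annotation removal

Detection is rule-based and deliberately pluggable (any callable
producing a mask can stand behind the same interface, so a learned
detector can be swapped in):

1. White top-hat with an 11×11 structuring element — larger than a text
   stroke, smaller than anatomy — isolates small bright structure.
2. Extent threshold 0.18 on the top-hat response defines candidate
   pixels; connected components are kept only if they look like
   characters: height within 1–8% of image height, width ≤ 30% of image
   width, stroke-like fill ratio (0.08–1.0; partial glyphs can be solid
   bars, hence the open top), area ≥ 4.
3. A peak filter requires each component's maximum top-hat response to
   reach 0.30: burned-in strokes are near display-white, so their
   response peaks far above the extent threshold, while smooth anatomy
   ridges (for instance the bright wedge at a lung's upper-outer corner)
   cross 0.18 but never peak that high. Thin slivers pressed flat against
   the frame edge are dropped as body-outline rim responses.
4. An arrangement filter keeps components near a border or collinear with
   another candidate — characters come in runs; isolated central blobs
   (jewelry, electrodes) do not.
5. The mask is dilated by 2 px, but halo pixels are kept only where the
   top-hat shows some brightness excess (≥ 0.045), so the margin covers
   sub-threshold spill without bleeding onto dark anatomy such as a lung
   apex under a corner marker.

**Inpainting** fills masked pixels by distance-ordered neighborhood
averaging — pixels are processed in increasing Euclidean distance from
the mask boundary, each taking the mean of its already-known 8-neighbors
— and then re-textures the fill with noise matched to the image
(robust MAD estimate of the residual against a 3×3 median filter, drawn
deterministically from the image + mask content). The noise matching is
not cosmetic: a flat fill is a mask-shaped scar that a downstream model
can learn from, which is precisely the artifact annotation removal is
meant to eliminate. Unmasked pixels are returned bit-identical; masks
covering more than half the image are refused with a review flag.

Outcomes against a truth mask are graded `complete` (≥ 99% of truth
pixels covered), `failed` (≤ 1%), `partial` otherwise, `none_present`
for an empty truth; `inpainted_in_lung` records any predicted pixel
inside the lung region that is not true annotation. On phantoms the lung
region is the generator's lung ellipses; on real data a central-60% box
stands in (documented heuristic).

## Stage 4 — projection and quality

**Projection.** A regularized logistic regression on engineered features:
32×32 anti-aliased intensities, a vertical-mirror symmetry score, and
row/column profile moments (1033 features). Features are centered but not
variance-scaled: all share the [0, 1] intensity scale, and per-feature
standardization would blow up low-variance regions (flat corners) into
huge z-scores on out-of-distribution inputs — exactly the regions
annotation removal empties. Training requires ≥ 50 images with both
classes; the fitted handle is versioned with a feature-spec hash and is
deterministic given the seed. The decision threshold defaults to 0.5.

Series Descriptions are parsed with an editable token table (frontal: PA,
AP, FRONTAL; lateral: LAT, LATERAL, LL, RL), case-insensitive on word
boundaries. Lateral tokens take precedence when both occur: combined
study descriptions ("PA AND LATERAL") usually attach to the lateral
acquisition, and calling a lateral film frontal is the costlier error.
The consistency check passes absent declarations and flags
`metadata_mismatch` otherwise; batch reports carry the token-coverage
fraction and mismatch rate.

**Quality.** Four no-reference scores, one per failure axis: sharpness
(variance of the discrete Laplacian), contrast (1st–99th percentile
spread), blur index (1 − high-frequency fraction of AC spectral energy
above 0.05 cycles/pixel, computed after a 3×3 median prefilter — detector
noise lands on top of any blur and would otherwise hide the
high-frequency deficit), and residual border fraction (re-running border
detection post-crop). Default thresholds are mean ± 3 SD of each score
over 200 clean synthetic images under the generator's default acquisition
conditions (sharpness_hi 7.0e-3, contrast_lo 0.564, blur_hi 0.9816,
border_frac_hi 0.05). They are calibration constants for the synthetic
domain, shipped in configuration and expected to be recalibrated for any
real image domain. Known blind spot, kept deliberately: thin scratch and
pixel-dropout artifacts barely move any of the four scores and are not
reliably flagged; a test documents this.

## Curation

Age fields resolve to numeric years (`"40-49"` → 44.5, the range
midpoint); unparseable values are missing. Rows missing any
stratification field (manufacturer, deviation index, sex, age, ethnicity)
are excluded and logged with the first missing field. One image per
patient is selected uniformly at random (seeded).

Partitioning into train/tune/test (0.64/0.16/0.20) stratifies jointly
over the five fields, binning age into decades and deviation index into
observed terciles; joint strata with fewer than 3 rows are coarsened by
dropping the deviation bin, then the age bin, then pooling. Within each
stratum rows are shuffled (seeded) and allocated by cumulative controlled
rounding: quotas are floored and leftover rows go to the splits with the
largest running deficit. With hundreds of small strata this self-balances
— a naive per-stratum largest-remainder hands the leftover to whichever
split has the biggest remainder at the common stratum size (at n = 3 that
is always the same split) and accumulates a systematic skew. A final
correction of at most one row per split makes the global sizes match the
Hamilton (largest-remainder) apportionment exactly while every stratum
stays within one row of its quota. No patient may span splits; the
partitioner asserts this.

## Evaluation

Seven metrics (AUROC, accuracy, precision, recall, specificity, NPV, F1)
are computed from explicit confusion-matrix arithmetic; AUROC is the
tie-averaged rank statistic. Undefined values (zero denominators,
single-class AUROC) are `None`, never silently propagated NaN.
Confidence intervals are percentile bootstrap (default n = 1000 seeded
case resamples, 2.5/97.5 percentiles); resamples where a metric is
undefined are skipped for that metric and the AUROC skip count is
reported. Percentile CIs were chosen over BCa for reproducibility and
simplicity.

Saliency is occlusion sensitivity: each patch (default 32 px, stride 16)
is replaced by the image mean and the absolute change in the model's
log-odds is accumulated over the patch footprint, then normalized to
[0, 1]. Log-odds, not probability: a confident classifier saturates the
probability scale and would show no sensitivity anywhere. Maps are
binarized at the 0.9 quantile for IoU against annotation masks (an
all-zero map binarizes to all-false); IoU of two empty masks is defined
as 1.0 (perfect agreement that nothing is present).

## The shortcut experiment

Three frontal-vs-lateral models are trained on the same synthetic cohort
in three preparations — original images, images cleaned by
detect-and-inpaint, and images with truth-box regions zeroed — and each
is evaluated on with-text, text-removed, and never-annotated test sets,
with full bootstrap metric grids, plus mean saliency-mask IoU per model
with paired-bootstrap difference CIs.

The experiment's conditions are chosen so that shortcut learning can
actually occur, because that is the phenomenon under study:

* Burned-in tokens correlate perfectly with the class (technique markers
  in practice are deterministic); the tokens are "PA" vs "LL", which have
  the same footprint, so the zero-intensity boxes of the zero-box variant
  carry no class information of their own.
* The anatomy signal is made imperfect: each phantom blends toward the
  opposite projection's prototype by a per-image ambiguity drawn from
  U(0.4, 1.5), where values above 1 cross the midpoint — the synthetic
  analogue of atypical films that genuinely resemble the other
  projection. Without irreducible anatomy error a linear model has no
  reason to lean on the token and no shortcut effect exists to measure.

Expected (and asserted) directional findings on seeded runs: the
original-trained model loses > 0.05 accuracy when text is removed at test
time; the two text-free-trained models are stable (≤ 0.05) across test
variants; the inpainted-trained model attains the lowest mean
saliency-mask IoU.

## The phantom generator

Phantoms are geometric, not anatomically realistic. A frontal phantom is
a body ellipse with two mirror-symmetric dark lung ellipses, a bright
mediastinal column, and a bright abdomen band; a lateral phantom has one
offset lung, an off-center spine band, and no mirror symmetry. Smooth
random blobs add texture. Everything a pipeline stage keys on is injected
explicitly with exact truth: glyph text from a built-in 5×7 block font
(no font dependency, pixel-exact masks), constant-value padding,
near-black collimation bands (0.02 ± 0.005), 90° rotations, Gaussian blur
and detector noise, and two vendor intensity curves
(`clip(offset + gain·x^γ)`; Vendor A = identity, Vendor B γ = 1.03,
gain = 0.90, offset = 0.12) with fixed per-vendor display windows mapping
the curve's output over the anatomy range [0.10, 0.92] onto the central
70% of the display band.

Generation order is: anatomy → blur → noise → vendor curve → text →
collimation → padding → rotation. Blur and noise precede the vendor
curve because they are acquisition-side effects in detector units;
burned-in text comes after everything photometric because annotations are
digital overlays on the processed image — rendering them crisp, at the
vendor's display-white level. (Blurring glyphs together with the anatomy
would leave a sub-threshold intensity ghost around each character that no
finite detection margin fully captures, and with perfectly
class-correlated tokens such a ghost is itself a learnable shortcut —
an artifact of the rendering order, not of annotation removal.)

Default cohort conditions: 50% frontal, 90% of films annotated, half of
films padded (4–16 px), each side collimated with probability 0.3
(8–28 px), 10% rotated, blur σ ∈ U(0, 1), noise SD ∈ U(0.005, 0.02), 10%
of rows with one missing metadata field, 15% repeat-patient rate, 60% of
Series Descriptions carrying a projection token with a 3% error rate.
These are plausible clinical-mix values chosen once; nothing in the
pipeline depends on them being exact.

What passing tests on phantoms do **not** show: performance on real
radiographs. The phantoms contain no pathology, no grid or scatter
physics, no vendor-specific LUT sequences, no overlapping anatomy under
annotations, and their text uses one synthetic font. The rule-based text
detector in particular is tuned to this family; on clinical data the
pluggable detector interface is the intended path to a learned detector.

## Problem sizes and determinism

Seeded synthetic benchmarks use 200–500 phantoms per property (500 for
crop-box exactness, 300 for annotation removal, 200 for rotation and
harmonization, 300 images for the shortcut experiment) — sizes at which
the binomial uncertainty of the asserted rates is comfortably below the
asserted margins. Every stochastic component (generator, splitter,
bootstrap, training) takes an explicit seed; pipeline reruns over the
same fixtures with the same configuration produce byte-identical JSON
reports, which the acceptance suite asserts.

## Known limitations

* The rotation score assumes an abdomen-bright, roughly centered subject;
  heavily atypical laterals occasionally defeat it (~2% on phantoms).
* The quality thresholds are domain calibrations, not universal
  constants; scratch/dropout artifacts are a documented blind spot.
* The collimation threshold is absolute on the stored scale; detectors
  whose unexposed level is not near-black (non-zero offset without a
  rescale intercept) would need the threshold adjusted.
* The projection model is a linear classifier on engineered features; it
  is the study instrument for the shortcut analysis, not a clinical-grade
  classifier.
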