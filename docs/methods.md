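# Methods

`echoquant` implements a fully automated 2-D echocardiography quantification
chain — per-view chamber segmentation with three U-net-family networks,
geometric derivation of clinical indices from the predicted masks, and the
agreement statistics used to validate such pipelines — exercised end-to-end
on a synthetic B-mode phantom generator so that no patient data is required.
This note records the models, the parameters that matter, and the design
choices made where the design was genuinely open.

## The phantom

Patient echocardiograms are emulated by a geometric phantom built so that
the downstream quantification formulas are exact in the continuum limit,
giving every derived quantity an analytic oracle.

**Geometry.** The LV is a prolate spheroid with long semi-axis `a = 2·b`
(a typical adult LV aspect ratio); its apical-view cross-section is a true
ellipse with area `A = π·a·b` and long axis `L = 2a`, so the single-plane
area-length volume `(8/3π)·A²/L` equals the spheroid volume `(4/3)·π·a·b²`
identically. The end-diastolic volume fixes `b` (EDV = `(8/3)·π·b³`); the
long axis is held constant over the cycle and the cavity cross-sectional
area varies sinusoidally between its diastolic and systolic values, so each
cine has exactly one end-diastole (phase 0) and one end-systole (phase 0.5)
and frame selection has an unambiguous ground truth. The LA is a smaller
prolate spheroid (aspect 1.4) below the mitral plane, modulated in
anti-phase (maximal at ventricular end-systole, minimum 55 % of maximum).
The A4C view adds RV and RA ellipses in the right-heart position; PSAX at
papillary-muscle level shows the LV cavity disc inside a concentric
myocardial ring of the requested wall thickness (papillary muscles are not
rendered inside the cavity, matching the annotation convention of excluding
them). Chambers are pairwise disjoint by construction and the generator
raises if a parameter combination would make them collide.

**Rendering.** Frames are sector-shaped 8-bit images: dark cavities
(mean 25), mid-gray tissue (70), bright myocardial ring (130) and a bright
LV endocardial rim (180), multiplied by unit-mean Rayleigh-distributed
speckle — the standard first-order B-mode speckle model; the exact
distribution is cosmetic, not load-bearing. Image quality is controlled by
`border_visibility ∈ [0, 1]`: a contiguous arc containing a fraction
`1 − border_visibility` of the endocardial boundary pixels (random position,
seeded) is replaced by tissue-level intensity, and the signal loss extends
~5 mm across the border so that degraded cines genuinely lose boundary
definition. The quality classes follow the percent-border-visualization
convention: good 67–100 %, fair 34–66 %, poor 0–33 %.

**Cohorts.** `generate_cohort` assigns quality classes by deterministic
largest-remainder allocation over the requested mix (so cohort composition
is exactly reproducible), draws `border_visibility` uniformly inside the
class band, and samples per-patient physiology around normal adult ranges:
EDV ~ U(90, 160) ml, EF ~ U(50, 70) %, LA volume 25–45 % of EDV, wall
thickness 8–12 mm. The default pixel spacing maps a 20 cm field of view
onto the image width. Everything (geometry, speckle, class assignment) is
a pure function of the seed; the same seed reproduces the dataset
byte-identically.

**What the phantom does not emulate.** Real speckle correlation and
point-spread anisotropy, valve/pericardial structures, foreshortened or
off-axis views, arrhythmia, translation of the heart through the imaging
plane, and real inter-patient shape variability beyond size/EF scaling.
Tests passing on phantoms therefore demonstrate the correctness of the
pipeline's machinery (training dynamics, geometry, statistics), not
clinical-grade segmentation of patient images.

## Data handling

Splits are by patient, never by frame, preventing leakage between frames
of one heart; sizes follow round(fraction·n) with the remainder to the
training set (500 patients at 80/10/10 give 400/50/50). k-fold
cross-validation partitions patients into near-equal folds by a seeded
permutation; each round uses k−1 folds for training+validation and one for
test. Images are resized (bilinear) to the network size — 512×512 in the
full-scale configuration — and min–max normalized to [0, 1] per frame
(constant frames map to zero); label maps are resized nearest-neighbour so
codes stay integral. The per-axis pixel spacing is rescaled by
`original_size / target_size` so physical measurements survive resizing.

## Segmentation networks

Three encoder–decoder architectures share a plain U-net decoder
(2×2 transpose-convolution upsampling, skip concatenation, two
conv–BN–ReLU stages per level) and differ in the encoder/bottleneck block:

* **unet** — two 3×3 conv–BN–ReLU stages;
* **res_unet** — the same two-stage path plus an identity shortcut
  (1×1 projection when the width changes), ReLU after the sum;
* **dense_unet** — two 3×3 stages whose inputs are the concatenation of
  all previous outputs in the block, fused back to the block width by a
  1×1 transition.

For fixed width the parameter counts order strictly dense > res > plain.
Block details the source architecture family leaves open (BN placement,
3×3 kernels, transpose-conv upsampling, block depth 2) follow the common
U-net convention and are asserted only as conventions, not inferences.

The networks and their backward passes are implemented directly on numpy
(im2col convolutions over BLAS matmuls, explicit gradients for every
layer), so the package is self-contained and runs identically on any CPU.
Gradient correctness is established by finite-difference checks per layer
and by single-image overfitting tests.

**Training recipe.** Pixel-wise cross-entropy, Adam with learning rate
1e-4, 200 epochs, mini-batch 5, training from scratch, per-epoch seeded
shuffling, and joint augmentation: independent 50 % up–down and left–right
flips plus rotation uniform in ±15° (small angles keep the sector
plausible; the mask is rotated nearest-neighbour). Model selection keeps
the weights with the best validation mean foreground Dice — a standard,
testable choice where the recipe leaves selection unstated; the snapshot
includes the BatchNorm running statistics, which are part of the inference
state. One model is trained per view, with label schemes
{bg, LV, LA} (A2C), {bg, LV, LA, RV, RA} (A4C) and
{bg, LV cavity, LV myocardium} (PSAX); prediction is per-pixel argmax with
ties broken toward the lower label code.

**Desk-scale preset.** The full-scale regime (512 px, 200 epochs, base
width 64) is impractical for routine CPU runs, so `desk_config` provides a
preset used throughout the test-scale experiments: 64 px inputs, 3 levels,
8 base channels, 8 epochs (10 in the training checks), learning rate
3e-3 (the larger step
compensates for the short schedule). On an 80-patient all-good phantom
cohort this preset takes each architecture past 0.95 test LV Dice in a few
minutes; the full-scale configuration remains available by config.

## Quantification

All geometry operates on the largest connected component per label, so
stray prediction pixels cannot corrupt measurements; components of fewer
than 3 pixels are treated as absent. Areas are pixel counts times physical
pixel area; the long axis is the extent of the component projected on its
principal axis (second-order moments in physical coordinates, hence
rotation-equivariant and anisotropy-aware), plus one pixel footprint.

* LV volumes: biplane area-length `V = (8/3π)·A_A2C·A_A4C/L` at ED and ES,
  with `L` the shorter of the two views' long axes (the guideline
  convention; a single available view degrades to the single-plane form
  and is flagged).
* LA volume: same method on the LA at ventricular end-systole (maximal
  LA), the guideline convention where the measurement frame is unstated.
* LV mass: area-length from PSAX papillary-level areas and the apical long
  axis — wall thickness `t = √(epi/π) − √(endo/π)`, myocardial volume
  `Vm = 5/6·[epi·(L+t) − endo·L]`, mass `1.05·Vm` with myocardial density
  1.05 g/ml.
* EF = 100·(EDV − ESV)/EDV.

RV/RA volumes are computable by the same single-plane machinery but are
not part of the standard report. ED/ES frames are selected as the frames
of maximal/minimal LV-cavity pixel area (first occurrence on ties).

## Agreement statistics

Dice and IoU are computed per structure per case and averaged over cases;
a structure absent from both masks scores 1.0 (correct absence), avoiding
0/0. The pairwise identity IoU = DSC/(2−DSC) holds exactly per pair but
not for averages of either — the test suite asserts both facts.

The ICC is the two-way random-effects, absolute-agreement,
single-measures form, ICC(A,1) = (MSR − MSE)/(MSR + (k−1)MSE +
k/n·(MSC − MSE)), with the F-based 95 % CI (Satterthwaite degrees of
freedom); it is cross-checked against an independent ANOVA decomposition
and against `pingouin`. Two raters are treated as a random factor.
Bland–Altman reports bias ± 1.96·SD of the paired differences (sample SD).
Paired t tests are two-sided; zero-variance differences return p = 1 with
a flag rather than NaN. Pearson p values use the two-sided t transform.

## Observer simulation

Human re-annotation is emulated by seeded smooth elastic jitter of the
truth-mask boundaries (Gaussian-filtered displacement fields, amplitude in
mm, nearest-neighbour resampling); the intra-observer repeat uses a
smaller amplitude (default 0.8 mm) than the second observer (1.6 mm),
encoding the assumption that one reader disagrees with themselves less
than two readers disagree. With these defaults at n = 100 the simulation
reproduces the qualitative pattern expected of the real study design:
inter-observer ICC below intra-observer ICC for every index, and EF the
least reproducible index because errors in EDV and ESV accumulate through
the ratio. The simulation is a labelled stand-in for human observers, not
a model of any particular reader.

## Numerical choices and degenerate inputs

Constant frames normalize to zero rather than dividing by zero; uniform
class scores decode to background (lowest label wins ties); empty strata
in the stratified table are reported absent; ICC on zero-variance ratings
raises a named error; compare-methods suppresses statistics below 3 pairs
with a warning. All randomness flows from explicit seeds
(`numpy.random.Generator`); training is deterministic given seed and data
order.

## Problem sizes in the test and acceptance runs

The shipped experiments use the desk-scale preset: the three-architecture
training check runs on an 80-patient all-good A2C cohort at 64 px and 10
epochs; the quality-stratification check on a 60-patient mixed PSAX
cohort (roughly equal thirds good/fair/poor) at 16 epochs with
validation-based model selection, asserting the poor ≤ good ordering on
the LV myocardium — the structure most exposed to endocardial dropout —
because the model must be converged for image quality, not training
noise, to limit accuracy, and because the phantom's limited shape
variability keeps the effect small (a few Dice points), so it is asserted
as a fixed-seed directional property, not a magnitude; the size-ablation
on nested 20/60/100 %
subsets at 4 epochs; the observer simulation on 100 patients at 128 px;
phantom index recovery on 50 phantoms at 256 px. These sizes were chosen
as the smallest at which the respective effects are stable.

## Known limitations

The networks are CPU-bound numpy; the full 512 px/200-epoch regime, while
configurable, is slow without an accelerator. The phantom's simplicity
makes segmentation easier than clinical data, so absolute Dice values here
do not transfer to patients. LV mass assumes the area-length shell model
with a circular PSAX cross-section; DICOM support is limited to frame
extraction and pixel-spacing calibration.
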