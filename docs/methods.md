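# Methods

This note documents the models, conventions and numerical choices
behind `noisematch`, in the order data flows through the package.

## 1. What the synthetic cohorts emulate

The package studies a domain-shift question: a lesion detector is
trained on images from a low-noise reconstruction and deployed on a
much noisier out-of-domain dataset, and we ask whether re-rendering the
training data at a noise level matched to the target domain recovers
performance.  Two cohorts are emulated:

* **Set1** (modern digital scanner): 83 subjects — 42 normal, 41
  abnormal carrying 134 hepatic lesions in total — rendered under five
  reconstruction profiles (Q.Clear-like plus list-mode re-
  reconstructions at 5/4/3/2 minutes of data, VPFXS-like).
* **Set2** (older analog scanner): 123 subjects — 67 normal, 56
  abnormal, 233 lesions — under a single OSEM-like profile.

Each "subject" is a 2-D axial slice through the liver: an elliptical
region of uniform background uptake (default 5.0 SUV, a typical normal-
liver DOTATATE value; configurable) in a 1.0-SUV surround, rendered by
default on a 128 x 128 grid at 2.5 mm in-plane spacing.  Clinical
volumes are 3-D; we work in 2-D because the mechanism under study —
matching background noise statistics between domains — does not depend
on dimensionality, and 2-D keeps every experiment trainable on a single
CPU.

A reconstruction profile is reduced to exactly two numbers:

* `target_cov` — the background coefficient of variation (COV =
  SD/mean of SUV in a normal-liver ROI) that the profile must
  reproduce: 0.091, 0.098, 0.102, 0.110, 0.121 for the five Set1
  profiles and 0.198 for Set2.
* `smoothing_fwhm` — a Gaussian kernel standing in for the
  reconstruction's effective resolution.  The VPFXS-like profiles use
  5 mm (their nominal post-filter); the Q.Clear-like profile uses
  6.5 mm (penalized-likelihood reconstruction smooths more than a
  5 mm-filtered OSEM image); Set2 uses 5.5 mm (same 5 mm filter, but
  coarser native voxels add effective blur).  Native matrix/voxel-size
  differences (256^2/192^2/128^2) are *not* re-gridded; they are folded
  into these widths so that noise level remains the only variable
  separating profiles, with explicit resampling available separately
  via `annotation.transfer_contours`.

Acquisition time is carried as metadata only.  Measured COV across
reconstructions does not follow the ideal inverse-square-root scaling
with acquisition time, so each profile is calibrated independently to
its printed COV rather than derived from a counting law.

## 2. Noise model and COV calibration

Voxel noise is a smoothed (hence spatially correlated) zero-mean
Gaussian field: `image = G_fwhm * (clean + a * N) |_{>=0}` where `N` is
unit white noise, `G` the profile's Gaussian kernel and `a` the
pre-smoothing amplitude.  No projection-space, Poisson or scatter
physics is simulated: the study design characterizes noise solely by
background COV, which this construction reproduces directly — that is
precisely what the generator is for, and nothing downstream depends on
any other noise property.

The amplitude `a` is calibrated per profile by Monte Carlo: 200 unit-
amplitude fields are smoothed and the sample SD inside the standard
background ROI is measured with the same estimator used for reporting;
`a = target_cov * background_mean / E[SD_unit]`.  Because the measured
SD is exactly linear in `a`, a single rescaling suffices (no iterative
search), and because the calibration uses the reporting estimator, the
estimator's small-sample bias cancels.  The Monte-Carlo standard error
of the calibration is ~1-2% of the target; the calibration is cached
per (profile, grid, ROI) and runs with a fixed internal seed so the
pipeline stays deterministic.  With `smoothing_fwhm = 0` the kernel is
the identity and `a = target_cov * mean` in closed form.

The background ROI is a 30 mm-diameter circle at the liver centre —
the standard normal-liver reference-region size for PERCIST-style
reads (diameter configurable).  When a subject has lesions, the ROI
shifts through a fixed list of interior offsets until it clears them.
Per-subject COV estimates from such a small correlated-noise ROI are
intrinsically noisy (relative SD ~20-30%, consistent with the across-
subject spreads the emulated study reports); 25-subject means carry a
~4-6% standard error, which is the dominant uncertainty in the
calibration targets.

Multi-profile (Set1) subjects are *paired renderings*: anatomy, lesion
set and the unit noise field are drawn once per subject, and each
profile only rescales the amplitude and changes the smoothing — the
defining property of list-mode re-reconstructions of one acquisition.
This also makes measured COV strictly ordered across profiles for a
fixed seed set, since amplitude ordering transfers to paired fields.

## 3. Lesions and gold annotation

Lesions are radially tapered bumps `(c - 1) * bg * (1 - (r/R)^2)_+`
added inside the liver, with radius R ~ U[4, 15] mm and peak contrast
c ~ U[2.0, 5.0] times background (the emulated study reports no lesion
size or contrast distributions; these are package choices).  The
contrast floor sits just above the modified-PERCIST annotatability
limit of the noisiest cohort (1.5 + 2 x 0.198 ~ 1.9), which matters
for the study design: a lesion population must include faint,
near-detection-limit foci for background noise level to interact with
detectability at all.  A population of uniformly bright lesions (say
>= 2.5 x background) is detected essentially perfectly at every noise
level considered here and exhibits no domain-shift effect, which
defeats the purpose of the generator.  Placement is
rejection-sampled: lesions stay inside the liver, keep a separation
margin of two smoothing SDs plus one voxel (non-confluence), and must
keep a supra-threshold core after the strongest smoothing in the
cohort; radii are additionally capped at half the minor liver semi-axis
so placement stays feasible on small grids.  Per-subject lesion counts
partition the cohort total near-evenly (within the required 1-10 per
abnormal subject), shuffled by the cohort seed.

Gold masks follow the modified PERCIST rule, `threshold = 1.5 *
SUVmean + 2 * SD` of normal liver background, applied to the
*noise-free* rendered signal, where the rule degenerates to
`1.5 * background`.  This replaces the human visual-confirmation step
with the generator's ground truth.  Components use 8-connectivity in
2-D (26 in 3-D) throughout the package.  Gold annotation keeps
components of any size; the 20-pixel filter applies to predictions
only.

## 4. Detector

A residual encoder-decoder maps SUV images (divided by a fixed
constant, 10.0 — per-image normalization would erase the very domain
shift under study) to per-voxel lesion logits: four residual blocks in
the encoder (channel width doubling at each of two stride-2 stages)
and four in the decoder, with two 2x2-stride-2 transposed-convolution
upsamplers and additive skip connections; 3x3 kernels, batch
normalization, ReLU, and a linear 1x1 output head, so prediction maps
are binarized at logit 0.  The published description fixes the block
and transposed-layer counts; channel widths, kernel sizes and
normalization are package choices sized to train in CPU-minutes.

The normalization choice is load-bearing.  Batch normalization
freezes its running statistics at inference, so a test-domain
intensity/noise shift propagates into the network — which is the
quantity under study.  Instance normalization (the obvious
alternative) re-standardizes each feature map per test image and
thereby performs built-in test-time domain adaptation; in control
runs it compressed the inter-condition spread substantially.  A
detector used to *measure* domain shift must not silently correct it,
so batch norm is the default (instance norm remains available in the
backend).

The loss is `BCE + Dice` with equal weights (no weighting is published;
equal is the common convention) and smoothing epsilon 1 in the Dice
ratio, making the empty-gold/empty-prediction case a zero-loss fixed
point.  Optimization is Adam at learning rate 3e-3 with a single step
decay (x0.3 at two-thirds of the epoch budget), batch size 8, at most
50 epochs with best-validation-F1 checkpointing and patience-10 early
stopping; 1e-3 is conventional but needlessly slow for the few
hundred optimizer steps a desk-scale epoch budget allows, and the
decay step removes most end-of-training run-to-run jitter.  Three
small-data safeguards matter at this scale: a trailing fragment
minibatch is padded by wrapping the shuffled epoch order (batch-norm
moments from 1-2 images are degenerate); early stopping may not fire
before a burn-in of 10 epochs (a near-initialization network can post
a lucky validation score while the loss is still falling steeply, and
restoring that checkpoint yields a degenerate detector); and because
pooled validation F1 over a small subject set is a coarse quantized
metric, an exact tie moves the saved checkpoint to the later,
further-trained state.  The network,
its gradients and the optimizer are implemented directly in NumPy
(float32, channels-last, convolutions as einsum contractions over
sliding-window views); every layer's backward pass is verified against
finite differences in double precision.  Training is a pure function of
the seed.

Inference post-processing: binarize logits at 0, label connected
components, discard components below 20 pixels (interpreted as 2-D
pixels in 2-D mode), relabel contiguously.

## 5. Scoring

Scoring is lesion-level.  Predicted and gold components are matched
one-to-one by the Hungarian algorithm on the pairwise IoU matrix,
maximizing total IoU (the published criterion fixes Hungarian matching
and the IoU > 0 rule but not the assignment cost; maximum total IoU is
the natural instantiation, with zero-overlap assignments discarded
afterwards).  Matched pairs are TP, remaining predictions FP,
remaining gold FN; PPV, sensitivity and F1 follow the count formulas
with 0/0 -> 0.  Test-set metrics pool counts over subjects before
forming ratios (micro-average), consistent with count-based
definitions; per-subject averaging is the plausible alternative and
would weight subjects rather than lesions.

## 6. Experiments and desk-scale conditions

Cohorts are split 60/20/20 into train/validation/test with overall
sizes round(0.6 n)/round(0.2 n)/remainder (83 -> 50/17/16), stratified
by abnormal status so small training splits cannot degenerate to
all-normal; one subject partition is shared by all profiles of a
cohort.  Replicate runs (default seeds 1-5) differ only in training
seed.  Per-run F1 values are compared with a two-sided Welch two-sample
t-test — runs are independent trainings, and pairing them by seed
index would assert a correspondence the seeds do not carry.  No
multiple-comparison correction is applied (raw p-values are reported),
matching the emulated analysis.

The two sweeps:

* **Noise sweep** — for each Set1 profile, 5 detectors are trained on
  that profile's training split and scored on the identical Set2 test
  subjects; an upper-bound condition trains on Set2's own training
  split.  A control mode scores every condition in-domain instead.
* **Sample-size sweep** — on the noise-matched profile, nested subject
  subsets (25% of the training split contained in 50%, contained in
  75%, in 100%; nesting isolates the sample-size effect from subset
  identity) are trained per run with the same validation and test sets
  throughout.

The sweep tests and worked examples run at desk scale: the default
compositions scaled by ~0.8 at constant internal ratios — Set1-like
66 subjects (33 normal / 33 abnormal, 107 lesions) and Set2-like 98
subjects (53 / 45, 187 lesions), preserving the original cohorts'
83:123 size ratio and hence the in-domain condition's proportional
data advantage — on 64 x 64 grids, base channel width 8, and a
deliberately reduced 12-epoch budget (burn-in 10, patience 6).  The
reduced budget is part of the emulated regime, not only a time
saving: the published experiments operate far from performance
saturation (their full-training F1 is ~0.71), and on these phantoms a
near-convergence budget saturates every condition and flattens both
sweeps, whereas the reduced budget keeps the task data- and
noise-limited.  A 60/20/20 split then gives
~40 training subjects per low-noise condition and a 20-subject shared
test split, and a full sweep (30 resp. 20 trainings) runs in about
ten minutes on one CPU.  The calibration targets and cohort-
composition checks always run at the full default sizes.

## 7. What passing tests do and do not show

The generator reproduces the *noise levels* (background COV) and
*composition* (subject and lesion counts) of the emulated study, and
the pipeline reproduces its *experimental logic* end to end — those
are the claims the passing tests certify.

The *effect sizes* of the clinical experiments are a different
matter, and the honest finding is that these phantoms express them
only weakly.  Two design constraints cap the inducible domain shift:
gold lesions must exceed the modified-PERCIST cutoff of the
noise-free background (otherwise they would not be annotatable, and
the gold standard would be ill-defined), which floors lesion salience
at roughly 2.5 standard deviations of even the noisiest background;
and the noise model is deliberately background-COV-only on a
homogeneous liver, so there is no anatomical texture for noise to
confound.  A competently trained detector is then largely robust
across the COV 0.091-0.198 ladder, and the inter-condition spread of
out-of-domain F1 sits near the 5-run seed noise; likewise the
sample-size curve saturates by a few tens of training subjects.
The strict directional test-suite checks on the two sweeps document
this: they assert the clinical study's orderings at phantom scale
and are expected to fail there, which is itself informative.
Phantoms additionally lack physiological uptake variation,
reconstruction artifacts, 3-D partial-volume structure, and any
spatial-correlation differences between scanners beyond what the
smoothing widths encode (only COV is matched across domains — whether
the real higher-noise scanner also differs in noise texture is
unknowable from summary noise statistics).  Absolute F1 values on
phantoms are therefore not comparable to clinical values.

## 8. Degenerate inputs and numerical conventions

* Sample SDs use the n-1 denominator everywhere.
* Paired COV tests: identical lists return (t = 0, p = 1); zero
  difference variance with nonzero shift returns p = 0 with a warning.
  Welch comparisons of identical zero-variance samples return p = 1.
* `segment_lesions` on an all-background image returns an empty mask
  (not an error); IoU of an empty component is an error.
* Contour transfer uses nearest-neighbour label resampling in physical
  coordinates, origin-aligned at voxel (0, 0); components shrinking
  below one target voxel are dropped with a warning.
* Training aborts with a diagnostic on non-finite loss; a zero-epoch
  budget returns the seeded initialization unchanged.
* All randomness flows from explicit integer seeds (cohort base seed,
  split seed, run seeds); per-subject seeds are `base_seed + index`,
  and rendering, training and evaluation are bit-reproducible given
  the same seeds on the same BLAS.
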