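# Methods

`mtldecode` implements a multivariate pattern analysis (MVPA) pipeline for
decoding scene identity and choice from high-resolution fMRI patterns in
medial-temporal-lobe (MTL) regions of interest — hippocampus (HC),
entorhinal cortex (EC) and parahippocampal gyrus (PHG), per hemisphere —
together with a synthetic experiment generator that reproduces the
statistical structure the analyses assume. This note documents the models,
the parameters that matter, the numerical choices, and what the synthetic
validation does and does not establish.

## Experimental design being modeled

A subject learns two highly similar scenes (A and B) and, in the scanner,
views the originals plus seven morphs spanning the continuum between them
(%A levels 100, 70, 60, 55, 50, 45, 40, 30, 0), 40 trials per condition in
pseudorandom order. Each trial is 2.5 s of stimulus (during which a choice
is registered), a 3 s confidence probe (ratings 1–3), and 2 s of rest;
EPI volumes arrive every TR = 3.5 s at 1.5 mm isotropic resolution. The
scientific questions are (i) whether local multi-voxel patterns in each
MTL region discriminate the two scenes, (ii) whether hippocampal
representations are more distinct (pattern separation), and (iii) what
happens on ambiguous trials — do hippocampal patterns snap to a stored
scene template (discrete attractor / global pattern completion) or occupy
intermediate configurations of their own?

## Trial-wise GLM (beta series)

BOLD time-series are modeled with one regressor per trial: a delta
function at the trial onset convolved with the canonical double-gamma HRF
(positive gamma with 6 s delay and 1 s dispersion, minus an undershoot
gamma with 16 s delay and 1 s dispersion scaled by 1/6; peak-normalized,
truncated at 32 s). Betas are ordinary least squares across all trial
regressors simultaneously, with nuisance columns (motion, intercept)
dropped from the returned trials × voxels beta series.

Assumptions and simplifications: noise is treated as i.i.d. (no AR
whitening) in both synthesis and estimation, so the OLS round trip is
exact on noiseless data and the (XᵀX)⁻¹ sampling-variance oracle holds
exactly; event duration is a delta rather than a 2.5 s boxcar. Designs are
checked for full column rank and rejected with the offending columns
named. A dataset may bypass BOLD synthesis entirely and feed true patterns
directly as betas — both paths produce the same `BetaSeries` type, and the
GLM path reproduces the direct path to ~1e-7 when noise is off.

Volumes are smoothed (when the BOLD path is used) with a separable
Gaussian, FWHM 3 mm by default on the 1.5 mm grid
(σ = FWHM / (2√(2 ln 2)) / voxel size per axis). Boundaries are
zero-padded and the kernel is truncated at 8σ — generous, so that the
Gaussian semigroup property (smoothing by a then b equals smoothing by
√(a²+b²)) holds to near machine precision for well-resolved widths.
Smoothing applies to time-series only; betas are never re-smoothed.

## Decoding: nested searchlight feature selection + linear SVM

All classification is binary, with a linear maximum-margin classifier
(hinge loss, fixed C = 1, no probability calibration). The two-step
procedure per region of interest:

1. **Feature selection (searchlight).** For every ROI voxel, a sphere of
   radius 3 voxels (Euclidean, in voxel index units; with isotropic
   1.5 mm voxels, index and mm spheres coincide) is clipped to the ROI.
   The sphere's trials × voxels pattern is scored by leave-one-out
   cross-validated accuracy of the linear SVM over the *training* trials
   only, giving an accuracy map. The voxels of the maximal-accuracy
   sphere are selected; when several spheres tie for the maximum, the
   union of all maximal spheres is used. Ties are compared on integer
   correct counts, never floats, so the union rule is exact.
2. **Classification.** An SVM is trained on the selected voxels and
   evaluated on the held-out data.

The outer loop is leave-one-trial-out: k equals the number of trials, each
trial is the test set exactly once, and feature selection is recomputed
inside every fold from that fold's n−1 training trials. The held-out
trial therefore never influences voxel selection — the property the
chance-calibration study verifies behaviorally (and which the deliberately
leaky all-trials variant, provided only as a diagnostic, demonstrably
violates).

**Labels are the subject's choices** everywhere, matching the decision
task (on 100% trials choices are near-ceiling so choice and stimulus
labels almost coincide); stimulus labels are available behind a flag for
diagnostics, and are undefined at the 50% level. Class imbalance among
choice-labeled morph trials is left as-is; class proportions are recorded
in every result.

Cross-condition analyses (train on 100% scenes, test on 50% morphs; train
on 50%, test on 100%; train on 50%, test on the other morph levels) run
feature selection and training on the full training condition set and
evaluate the test condition in one pass. The training-set-only selection
rule is a design choice: it is the only scheme that keeps the test
condition unseen end to end. Decoding runs per hemisphere and accuracies
are averaged across hemispheres.

### SMO implementation note

The nested procedure costs (outer folds) × (ROI voxels) × (inner folds)
SVM fits — hundreds of thousands of fits on problems of ~80 trials.
General-purpose SVM wrappers spend ~1–2 ms per call at this size, so the
package carries a compact SMO solver for the C-SVC dual (second-order
working-set selection, shrinking, KKT stopping tolerance 1e-3 — the same
optimization problem and tolerance as libsvm). Leave-one-out and
leave-two-out sweeps warm-start each subproblem from the full-data
solution with a gradient-guided repair of the equality constraint.
Correctness is pinned against sklearn's libsvm binding in the test suite
(identical predictions away from the decision boundary, decision values
agreeing to the stopping tolerance, and exhaustive agreement of the
leave-two-out tables with per-pair refits). A decision value of exactly 0
deterministically predicts the first class in label sort order.

The per-fold searchlight maps are assembled from a shared leave-two-out
table: one fit on trials \ {i, j} predicts both i and j, and fold i's
inner leave-one-out results are exactly row i of the table (no fit in
that row ever sees trial i). This halves the fit count relative to naive
recomputation while remaining algebraically identical to it.

Two speed knobs exist for simulation studies, both **off** by default:
sphere-center striding (evaluate centres on a subgrid) and inner-fold
subsampling (score spheres on a fixed, evenly spaced subset of trials).
They reduce how many spheres/folds are evaluated; the nesting itself is
never relaxed.

## Synthetic data generator

The generator emulates the features of the experiment the analyses rely
on; its defaults are the study conditions.

* **ROI masks.** Compact connected blobs grown voxel-by-voxel
  (distance-ordered flood fill) around separated seed points per
  hemisphere; default voxel counts HC 1093, EC 252, PHG 277 (the average
  manual-segmentation EPI voxel counts), exactly met and pairwise
  disjoint. Test-scale masks just request smaller counts.
* **Behavior.** P(choose A | x %A) = lapse/2 + (1−lapse)·logistic(slope·(x−bias)),
  defaults slope 0.2 per %A, bias 50 %A, lapse 0.02 — a sigmoid with
  near-ceiling accuracy at the originals (~98–99%) falling to 0.5 at the
  50% morph. Reaction time grows linearly with ambiguity
  (1 − 2|P−0.5|): 0.6 s base + 0.8 s × ambiguity, log-normal jitter
  (σ=0.15), clipped to the 2.5 s response window. Confidence thresholds
  |P−0.5| ≥ 0.4 → 3, ≥ 0.15 → 2, else 1, with a 20% chance of a ±1
  ordinal flip — reproducing the qualitative profile: confident and fast
  at the originals, unsure and slow near 50%. The same model governs
  100% trials (no learning dynamics are modeled).
* **Voxel patterns.** Scene templates are zero everywhere except inside a
  few local clusters (default 3 clusters of radius 2 inside each
  full-scale ROI) where template values are i.i.d. N(0, amplitude²) —
  scene identity is thus a local multi-voxel code a radius-3 searchlight
  can find, on a zero baseline. A trial's pattern is its geometry
  template plus i.i.d. N(0, noise_sd²) voxel noise.
* **Representational geometries for morph trials.**
  - *attractor*: a morph trial's pattern **is** the chosen scene's 100%
    template (global pattern completion to a stored state).
  - *intermediate*: morph patterns are drawn around per-level,
    per-choice family templates built as
    √c·(choice family core) + √(1−c)·(level-specific jitter), with
    c = `morph_family_correlation` (default 0.8). Family cores are drawn
    independently of the scene templates, so morph states correlate with
    the choice and with each other across levels, but not with either
    100% template.
  100% trials always express the stimulus template (with the ~1% lapse
  trials mislabeled relative to their pattern, as in real choice data).
* **Reproducibility.** One root seed; per-component streams
  (trial order, behavior, templates, noise) derived deterministically, so
  datasets are bit-reproducible.

What the generator does **not** emulate: spatially correlated or
temporally autocorrelated noise, baseline/drift structure, physiological
artifacts, subject motion, or anatomically realistic ROI shapes. Passing
the validation battery therefore shows the *pipeline* is correct and
calibrated under its stated assumptions — not that real MTL data would
yield these effect sizes.

## Group statistics

Per-subject, per-ROI accuracies (hemisphere-averaged) are tested against
the two-class chance level 0.5 with a one-sample two-sided t-test (the
test is a package decision; zero variance exactly at chance returns
t = 0, p = 1 with a warning). Regions are compared with a one-way
repeated-measures ANOVA over the ROI factor (statsmodels `AnovaRM`
backend, verified against an explicit sums-of-squares decomposition in the
tests), with paired t-test follow-ups reported uncorrected and
Holm-adjusted. Degrees of freedom follow the standard subject-level
RM-ANOVA (k−1 and (n−1)(k−1)).

The psychometric fit is a Bernoulli maximum-likelihood fit of the same
logistic-with-lapse model (L-BFGS-B, four starts, bounds |slope| ≤ 10,
bias ∈ [0, 100], lapse ∈ [0, 0.45]); perfectly separable choice data push
the slope to its bound and are flagged `at_ceiling`.

## Validation battery and problem sizes

`scripts/acceptance.py` (and `tests/test_acceptance.py`) recompute, from
fresh synthetic data each run:

* **Sphere geometry** — radius-3 interior spheres hold exactly the 123
  integer offsets with squared norm ≤ 9 (brute-force enumeration), and
  clip correctly at ROI borders.
* **Chance calibration** — 50 independent null experiments (80 trials,
  ~100-voxel ROI, zero-amplitude templates): nested decoding must average
  to 0.5 within 3 Monte-Carlo SEs; the leaky all-trials variant must
  exceed 0.5 significantly. Run in reduced nested mode (stride-3
  centres, 20 inner-fold trials), which leaves the nesting faithful.
* **Signal recovery** — accuracy 1.0 on noiseless separable data
  (noiseless end to end: zero pattern noise and lapse-free saturated
  choices, so labels match patterns exactly); median
  accuracy strictly increasing over amplitudes 0.5/1.0/2.0 at noise SD
  1.5 (7 seeds each, 16-trial sessions) — amplitudes chosen on the
  rising part of the dose-response curve to avoid ceiling compression.
* **Geometry dissociation** — 12 synthetic subjects per mode:
  attractor-mode train-100→test-50 above chance (3-SE criterion);
  intermediate-mode train-100→test-50 at chance while train-50→other
  morphs is above chance.
* **GLM round trip** — noiseless recovery below 1e-8; empirical beta
  variance within 15% of the (XᵀX)⁻¹ oracle at 5 s and 15 s spacings.
* **Group-stat oracles** — t and F equal closed forms; F = 0 for
  identical columns; type-I rate of the above-chance test within 3
  Monte-Carlo SEs of 0.05 over 20,000 binomial-null replicates (enough
  replicates that the estimate reflects the test's true level rather
  than simulation noise).
* **Psychometric recovery** — generating slope/bias recovered within 15%
  (median over 20 seeds) from 40 trials per level × 16 subjects.

Sizes were chosen so the whole battery completes in minutes on one CPU;
every quantity is measured at run time from data generated under the
stated conditions.

## Known limitations

* The pessimistic small-sample bias of leave-one-out with near-balanced
  classes (holding out a trial makes its class the training minority) is
  visible at chance-level signal: per-session null accuracies scatter
  widely and slightly below 0.5; the calibration study averages over
  sessions, as group analyses do.
* Cross-condition accuracy on intermediate-mode data is strongly bimodal
  per subject (the random family templates land on one side of the
  learned boundary or the other); only its subject average is
  interpretable, which is how it is tested.
* No multiclass decoding, nonlinear kernels, probability outputs, AR
  noise models, or whole-brain searchlight products: the searchlight here
  is a feature-selection device inside ROIs, not an end product.
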