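# Methods

## Scientific setting

Smooth pursuit eye movements (SPEM) — the continuous tracking of a
slowly moving target — are among the best-replicated sensorimotor
markers in psychosis research. `spemlab` implements a complete analysis
chain for the standard horizontal pursuit battery: a triangular-wave
(full-ramp) task probing sustained, prediction-driven tracking, and a
foveo-petal step-ramp (Rashbass) task in which the target steps a small
distance away from fixation and ramps back through it, so pursuit can be
initiated without a catch-up saccade. Four measures summarise a
subject's performance:

| measure | task | definition | units |
|---|---|---|---|
| predictive maintenance gain | triangular | median eye velocity / target velocity, 300–840 ms after each direction reversal | ratio |
| early maintenance gain | step-ramp | same ratio, 350–550 ms after motion onset | ratio |
| initial eye acceleration | step-ramp | robust regression slope of eye velocity over the 100 ms after acceleration onset | deg/s² |
| pursuit latency | step-ramp | time from target motion onset to eye acceleration onset | ms |

A nested cross-validated classifier is trained on these four measures to
separate psychosis probands from healthy controls, and the frozen model
is applied to external cohorts.

## Stimulus model

Targets move at 18.7 deg/s; the triangular wave has a 1200 ms ramp
period; the step-ramp steps 2.4 deg against the upcoming ramp direction,
so the target re-crosses centre 2.4/18.7 s ≈ 128 ms after onset.
Sampling is 500 Hz. A session comprises 48 analysable triangular and 32
analysable step-ramp trials plus attention trials (step-ramps at 9.7 or
26.6 deg/s) making up 30 % of the total; attention trials carry an
`analysis_eligible=False` flag rather than being discarded, so the
extractor's trial filtering is itself testable.

Two small geometric choices were genuinely open:

* The sweep amplitude is derived from the ramp period
  (18.7 × 1.2 / 2 = ±11.22 deg) rather than fixed at a round ±12 deg;
  the analysis windows are defined relative to the 1200 ms period, which
  makes the period the binding quantity. A different excursion can be
  configured.
* The triangular target starts from centre (position continuity), so
  the first reversal occurs half a period after motion onset and
  subsequent reversals every full period. Reversal times are stored
  explicitly per trial and the gain windows anchor on them; windows are
  only taken after reversals followed by a full ramp.

Time is milliseconds from trial start; positions are horizontal gaze
angles in degrees, rightward positive; every trial carries its own
`motion_onset` (default 400 ms of fixation, leaving the 200 ms
pre-onset rest interval fully recorded).

## Eye-trace generator

The trace simulator is the generative inverse of the extraction chain,
with every parameter known:

* the eye rests until `motion_onset + latency`, then its velocity rises
  linearly at the subject's `true_accel` until reaching the gain-scaled
  target velocity: the early gain governs the first 600 ms of step-ramp
  trials (feedback-driven phase), the predictive gain everything else;
  reversals of the triangular wave are tracked predictively
  (instantaneous velocity reversal after the initial acquisition);
* catch-up saccades (minimum-jerk velocity profile, 30–60 ms, amplitude
  equal to the accumulated position error) fire when the position error
  has exceeded the subject's threshold continuously for a 150 ms
  sensorimotor delay. The delay matters: with an instantaneous trigger,
  a sub-unity early gain would place a saccade inside the open-loop
  analysis window on *every* step-ramp trial, extinguishing the
  acceleration measure by construction;
* blinks are runs of invalid samples (100–300 ms uniform) at a Poisson
  rate per second; measurement noise is additive Gaussian position
  noise.

Defaults (gain 0.93/0.79, acceleration 80 deg/s², latency 176 ms) are
healthy-control-like values; noise_sd defaults to 0.01 deg, typical of
video-oculography after calibration.

## Cohort feature generator

Because raw clinical recordings are not redistributable, cohort-level
analyses run on synthetic feature tables drawn from the published
group-wise means/SDs of each study cohort (encoded in
`spemlab.cohorts`), truncated to physical ranges (gains in (0, 1.5],
acceleration > 0, latency in [80, 400] ms; draws outside the range are
redrawn), with per-measure missingness (0 %, 0.51 %, 1.23 %, 0.51 % in
the training cohort). Measures are drawn **independently** per subject;
the real between-measure covariance is unknown. This is the generator's
central limitation: independent features carry more joint information
than correlated ones, so classifiers trained on these tables land in the
upper part of the plausible accuracy band rather than at the published
point values. Passing tests therefore demonstrate correctness of the
pipeline mechanics and calibration, not reproduction of clinical effect
sizes. A between-feature correlation matrix can be supplied (Gaussian
copula) when better information exists.

## Extraction chain

1. **Low-pass filter.** Gaussian kernel with σ chosen so the amplitude
   response is −3 dB at 30 Hz (σ_t = √(ln 2)/(2π f_c) ≈ 4.4 ms);
   zero-phase, edge handling by nearest-value extension, so constants
   and interior ramps pass unchanged.
2. **Velocity.** Central *median* differentiation over a 9 ms span: the
   median of the symmetric central-difference slopes over all lags
   fitting in the span (lags 1 and 2 at 500 Hz). Exact on lines; halves
   the excursion caused by a single-sample glitch relative to the plain
   central difference.
3. **Blink mask.** Maximal invalid runs padded by 50 ms per side
   (eyelid artifacts straddle signal loss).
4. **Saccade mask.** Samples deviating from a running pursuit estimate
   (101 ms median filter) by > 30 deg/s, or with |acceleration| >
   2000 deg/s², sustained ≥ 6 ms; runs are extended to the flanking
   acceleration zero-crossings (capped at 30 ms — without the cap the
   extension would walk through the entire constant-sign acquisition
   phase) and padded 10 ms. Thresholds follow common video-oculography
   practice and are config-exposed.
5. **Gains.** Direction-rectified unmasked velocity samples inside the
   window are pooled across trials; gain = pooled median / 18.7. Trials
   contributing < 25 % of their window are dropped; a measure with no
   contributing trial is missing, not an error. Windows are half-open
   `[start, end)` in ms relative to their anchor.
6. **Acceleration onset.** Velocity is Savitzky–Golay smoothed
   (order 3, frame 63 — exact on cubics); resting mean μ and SD σ come
   from the −200…+100 ms window around motion onset (σ floored at
   0.1 deg/s so the threshold never collapses to zero on noiseless
   input); the detection criterion is rectified velocity > μ + 3.2 σ
   sustained ≥ 20 ms, with the onset required to fall 80–400 ms after
   motion onset (earlier = anticipatory, later = absent pursuit; the
   trial is dropped). The *reported* onset back-projects the bisquare
   regression line fitted over the 100 ms after the crossing to its
   intersection with μ. The raw threshold crossing carries two
   systematic errors that do not cancel — it is late by (threshold
   height)/(true acceleration) ≈ 4 ms at 80 deg/s², and early by the
   smoothing anticipation of the 126 ms Savitzky–Golay frame
   (≈ −10 ms) — measured net bias −8…+2 ms across 40–100 deg/s².
   Back-projection removes both on noiseless corners (residual
   < 0.5 ms) and is the standard refinement for pursuit-onset timing.
   The refinement falls back to the raw crossing if the fitted slope is
   non-positive or the correction exceeds 60 ms.
7. **Initial acceleration.** Bisquare IRLS slope (tuning constant
   4.685) of rectified smoothed velocity on time over
   [onset, onset + 100 ms); requires ≥ 80 % of the window unmasked.
8. **Aggregation.** Gains are pooled sample medians across trials
   (matching "median eye velocity over all trials"); onset-derived
   measures are computed per trial — onsets are not alignable across
   trials — and aggregated by the median for robustness.

Round-trip accuracy on noiseless sessions: gains ± < 0.005, latency
± < 1 ms, acceleration + ≈ 2 % (slight overestimate from residual
corner curvature inside the regression window); tolerances widen
gracefully with position noise.

## Classification protocol

Training tables hold the four measures, a binary group label
(positive class = psychosis) and optional covariates. The pipeline per
training partition is scale → impute → balance → reduce → classify:
z-scaling; median imputation of missing values on the scaled scale;
class balancing by random undersampling or SMOTE (the choice is a
hyperparameter); PCA with 1–4 components (4 = retain all; the component
count is a hyperparameter). Classifier families: SVM (linear/rbf,
C ∈ {0.1, 0.3, 0.5, 0.7, 0.9, 1}), random forest, Gaussian naive
Bayes, logistic regression, AdaBoost — all otherwise at library
defaults. Selection is by mean balanced accuracy over a 10-fold
stratified inner cycle; generalization is estimated by a 3-fold
stratified outer cycle. Ties on the inner score go to the first
configuration in a fixed enumeration order. All preprocessing is fit on
training partitions only; balancing is never applied to a test
partition. The deployable model is the configuration winning a final
inner search on the full sample, refit on all rows (the standard
reading of "apply the best performing model externally").

SMOTE and random undersampling are implemented in `spemlab.classify`
(on scikit-learn's `NearestNeighbors`): synthetic minority samples
interpolate between a minority point and one of its 5 minority
neighbours.

**Permutation test.** p = (1 + #{permuted BAC ≥ observed}) / (n_perm+1).
`mode="full"` re-runs the whole nested search per permutation;
`mode="fast"` freezes the observed winning configuration and
re-evaluates only the outer cycle — an approximation that is exact when
the grid has a single configuration and anti-conservative otherwise
(hyperparameter selection is not re-done under the null). The type-I
calibration check uses a single-configuration grid, where fast mode is
exact.

**External validation.** Rows with any missing measure are dropped and
counted; the remainder pass through the frozen stages; the model is
never refit. When both training labels are present, balanced accuracy /
sensitivity / specificity are reported; otherwise per-group
predicted-label tables.

**Variants.** Within-psychosis pairwise runs (SZ/SAD/BP), a gains-only
feature subset, a stratified random 50 % subsample, and pooled-cohort
training all reuse the trainer unchanged.

## Metrics and reporting

Sensitivity = TP/(TP+FN), specificity = TN/(TN+FP), balanced accuracy =
their mean, LR+ = sens/(1−spec), LR− = (1−sens)/spec, all on the percent
scale. Values are kept at full precision internally and rounded half-up
to two decimals only at report time; fold likelihood ratios are averaged
per fold, not recomputed from mean sensitivity/specificity — the order
matters at the second decimal. Confound correlations use tie-corrected
Kendall τ-b on pairwise-complete observations (dose covariates are
heavily tied at zero); families of four tests are corrected by the Holm
step-down procedure.

## Problem sizes and numerical choices

* The simulated training cohort reproduces the study composition
  (305 + 674 subjects); nested training over the full grid takes a few
  minutes on one core.
* Type-I calibration uses 200 null datasets of 60 subjects with 19
  permutations each (α = 0.05 is then exactly attainable as p = 1/20).
* Savitzky–Golay frames are clipped to odd lengths not exceeding the
  series; degenerate windows return missing values rather than raising.
* All generators and the classifier derive their randomness from a
  single integer seed; repeated runs are bit-identical.

## Known limitations

* Independent cohort features (see above) — accuracy bands, not point
  reproduction, are the meaningful check for simulation-trained models.
* The trace simulator does not model pupil signals, binocular data,
  vergence, blink-adjacent position artifacts, or smooth pursuit during
  target blanking; blanked attention trials are represented only as
  ineligible fillers.
* Saccade-detector thresholds are conventional defaults, not fitted to
  any particular recording device.
* Calibration-trial quality control between blocks is not modelled; no
  accept/reject rule is defined for it.
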