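# Methods

## The analysis problem

In an eight-alternative response task (8ART), one of eight symbols cues a
response with one of eight fingers on force-sensitive keys; a keypress
registers when its force exceeds 40 cN.  The experiment has two parts: a
no-self-evaluation part (7 blocks, 394 trials, of which the first two
blocks are practice) and a self-evaluation part (11 blocks × 64 = 704
trials) in which every response is first evaluated as correct/erroneous
(limit 3,000 ms) and then rated for certainty (1–4).  Responses slower
than 1,200 ms are excluded from analysis.  The package quantifies three
families of error-monitoring measures from such experiments:

1. **ERP components.**  Response-locked epochs (−100…+800 ms, 500 Hz) are
   re-referenced to linked mastoids, baselined on the 100 ms before the
   response, blink-corrected by EOG regression, cleaned of ±100 µV
   artifacts, and transformed to current source density (CSD).  The
   error(-related) negativity Ne/c is the mean of the five samples around
   the negative peak at FCz within 0–150 ms; the error positivity Pe/c is
   the analogous positive-peak mean at Cz within 150–300 ms, plus the
   plain window mean over 150–300 ms.  No spectral filters are applied
   anywhere.

2. **Behavioral metrics.**  Response types (signaled/non-signaled ×
   correct/error) from accuracy × self-evaluation; multiple responses
   (force > 40 cN on more than one key); the robust pre-post RT
   difference around target trials (RT_post − RT_pre, positive =
   post-error slowing); post-response accuracy; immediate error
   correction (a suprathreshold press of the target key on an error
   trial); evaluation RT and certainty summaries.  Participants enter a
   response-type analysis only with more than six trials in every cell.

3. **Time-resolved decoding.**  Epochs −900…+200 ms (baseline: 100 ms
   before the *stimulus*) are cut into 110 non-overlapping 10-ms windows
   of five samples; each window yields one spatio-temporal feature vector
   per trial (all scalp channels × 5 samples, channel-major).  A linear
   SVC (libsvm, C = 1, features z-scored with training-fold statistics)
   is evaluated under repeated stratified k-fold cross-validation
   (default 10 × 10 = 100 classification processes, averaged).  Chance is
   estimated *empirically* by re-running the identical pipeline on
   label-shuffled data.  Second-level inference: per window, a paired
   two-sided t test of accuracy against its own empirical chance across
   participants, Bonferroni-corrected over windows.  For the time-on-task
   analysis, each condition is split at its median trial into parts
   1.1/1.2/2.1/2.2; each of the six part-pair contrasts gives a
   per-participant decoding-group score: the mean over windows of
   (accuracy − chance), in percentage points.

## The synthetic generator

No public recordings exist for this design, so the package ships a
generator that produces complete experiments with known ground truth.
All effects are additive on top of spatially correlated 1/f Gaussian
noise, so subtracting a same-seed null run isolates any injected effect
exactly, and every analysis stage can be validated by parameter
recovery.

* **Components** are half-cosine (raised-cosine) bumps peaking at the
  window midpoint under spherical-Gaussian topographies (FWHM 70°)
  centred at FCz (Ne) and Cz (Pe); amplitudes are per response cell
  (defaults: Ne −8/−7/−2 µV for signaled errors / non-signaled errors /
  correct; Pe +8/+5/+2 µV).  The paper-level quantification windows and
  electrodes are fixed; the waveshape itself is a modelling choice — only
  its sampled 5-point peak mean matters for recovery tests, and that is
  available in closed form.
* **Condition pattern**: a rank-1 random spatial pattern present only in
  self-evaluation trials, switching on at a configurable onset before the
  response (default −550 ms) and sustained until the response, with an
  optional linear rise (default 0 ms).  A step onset makes the decoding
  onset a sharply recoverable parameter; a pattern that ramped gradually
  from onset to response would make "first decodable window" intrinsically
  ill-defined at any finite SNR.
* **Time-on-task drift**: a second random spatial pattern whose amplitude
  grows linearly with the global block index across the whole session
  (default 0.3 µV RMS per block), with a slow temporal profile across the
  epoch so baseline correction does not null it.
* **Blinks**: raised-cosine waveforms (300 ms, 200 µV) on vEOG at random
  epoch times, propagated to each EEG channel with coefficients b_ch
  (frontal-dominant by default, configurable per channel); occurrence
  times are recorded for recovery tests.
* **Behavior**: per-accuracy lognormal RTs (mean ≈ 800 ms, ~9% beyond the
  1,200-ms limit), error rate 0.12, post-error slowing +40 ms, a
  signaling model P(evaluate "correct" | accuracy, multiple-response)
  that lowers error signaling when multiple responses occur (so most
  non-signaled errors carry an immediate correction press), per-type
  evaluation-RT and certainty distributions, and per-key peak forces
  (correct responses more forceful than errors).

What the generator does **not** emulate: overlapping activity from
adjacent trials, non-stationary noise, muscle/channel artifacts other
than blinks, realistic force time courses (peak force only), saccade
artifacts on hEOG, or a nonlinear practice curve.  Passing recovery
tests therefore demonstrates correctness of the estimators under the
stated forward model, not robustness to every pathology of real EEG.

## Numerical choices

* **CSD**: Perrin-style spherical-spline surface Laplacian, stiffness
  m = 4, regularization λ = 1e−5, 50 Legendre terms, head radius 10 cm
  (units µV/cm²); the spline system is solved with the exact
  sum-to-zero constraint via an augmented linear system.  Electrode
  positions come from the standard 10-05 montage projected on a
  least-squares sphere; the two primed central sites are normalized
  flank midpoints.
* **Ocular correction**: single propagation coefficient per (EOG, EEG)
  channel pair, estimated by pooled least squares on single trials after
  subtracting the event-related average from both signals, then applied
  to the raw signals.  The blink/saccade distinction of the original
  procedure is omitted; the average-subtracted regression is its core.
* **Artifact rejection** uses a strict inequality (a sample at exactly
  ±100 µV survives) on scalp channels only, before CSD.
* **Window conventions**: component windows are endpoint-inclusive;
  decoding windows are consecutive half-open 5-sample blocks from the
  start of the analysis window, trailing remainder dropped.  Ties in
  peak search resolve to the earliest latency (logged).
* **Decoding**: class balancing subsamples the majority class per
  repetition; folds are class-stratified (so test folds stay balanced —
  with unbalanced random folds the null accuracy of cross-validation is
  biased below 0.5); MVPA decodes the mastoid-referenced signal by
  default with a CSD switch (`apply_csd_for_mvpa`); whether the 100
  classification processes are 10 × 10 is adopted as such.
* **Inference**: Greenhouse–Geisser ε is applied when Mauchly's test
  rejects sphericity at 0.05; within-subject Tukey HSD uses the
  studentized range on the rm-ANOVA error term; the pre-post RT contrast
  supports one-tailed Bonferroni t tests.  Component peaks are searched
  on participant-level (not grand) averages, since amplitudes enter
  repeated-measures ANOVAs per participant.

## Simulation-study problem sizes

The canned studies in `errmon.studies` fix these configurations:

* *Component recovery*: 400 trials (error rate 0.5 → ~200/cell), 10
  channels, noise 5 µV; expected values are closed-form sampled bump
  means.
* *Ocular recovery*: 144 trials, 12 channels, blink rate 0.9,
  coefficients 0.05–0.3.
* *Onset recovery*: cohorts of 20 participants, 8 channels, 40
  trials/condition, pattern amplitude 8 µV on 5 µV noise, analysis
  window −650…−50 ms, reduced cross-validation (3 folds × 1 repetition,
  2 shuffled-label runs — unbiased, just noisier than the 10 × 10
  default).
* *Type-I calibration*: cohorts of 20 participants, 4 channels, 26
  trials/condition, 8 windows, pure-noise epochs decoded raw.
* *Decoding groups*: the full 7 + 11 block geometry at 12 trials/block,
  10 channels, condition amplitude 2.6 µV and drift 1.4 µV/block.  These
  amplitudes place all six contrasts in the rising part of the accuracy
  curve: the ordering test needs the condition effect to dominate a
  1.5-block drift-distance handicap while the 2.5-block difference
  between medium and short cross-distances stays visible, which is
  impossible once accuracies saturate near 100%.

The reduced cross-validation and window counts change only the variance
of the accuracy estimates, not their expectation; they are what makes a
full recovery study a minutes-scale computation on one CPU.

## Known limitations

* The Gratton-style correction slightly attenuates genuine EEG that
  covaries with EOG residuals; with the generator's independent noise
  this bias is negligible, on real data it is the method's known cost.
* The greedy RT matcher does not guarantee globally optimal pairing;
  with a 50-ms caliper it removes planted shifts of the size seen in
  practice (≈30 ms) to below 5 ms.
* `rm_anova_2x2` reports the pingouin two-way table as-is; only the
  one-way wrapper carries the full ε/post-hoc contract.
* Decoding-group scores inherit the sign convention accuracy − chance;
  strongly anticorrelated window noise can produce slightly negative
  scores under the null, which is expected behavior, not a bug.
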