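# errmon

Error-monitoring EEG analysis for eight-alternative choice (8ART)
experiments: response-locked ERP component quantification, behavioral
error-monitoring metrics, and time-resolved multivariate decoding with
empirical chance — driven by a synthetic experiment generator with known
ground truth, so the whole pipeline is testable without any recordings.

## Who this is for

Researchers studying performance monitoring — how the brain detects its
own errors, and how an explicit self-evaluation of response accuracy
changes that process.  In the 8ART, one of eight symbols cues one of
eight fingers on force-sensitive keys (responses register at 40 cN); a
first, no-self-evaluation part (7 blocks / 394 trials) is followed by a
self-evaluation part (11 blocks / 704 trials) in which each response is
evaluated as correct or erroneous and rated for certainty.  Errors split
into *signaled* (evaluated as errors) and *non-signaled* (evaluated as
correct).

## What it computes

* **Ne/c and Pe/c.**  On CSD-transformed, response-locked averages, the
  error negativity is the mean of the five samples around the negative
  peak at FCz in 0–150 ms; the error positivity the analogous
  positive-peak mean at Cz in 150–300 ms, plus the plain 150–300 ms
  window mean.  Preprocessing: linked-mastoid re-reference, −100…0 ms
  baseline, Gratton-style EOG regression, ±100 µV artifact rejection,
  spherical-spline surface Laplacian (m = 4, λ = 1e−5) — and no
  spectral filtering anywhere.
* **Behavior.**  Response-type rates, multiple responses (> 40 cN on
  more than one key), peak force, evaluation RT, certainty, post-response
  accuracy, immediate error correction, and robust post-error slowing
  (pre-post RT difference: RT after minus RT before each target trial).
* **Decoding.**  In every 10-ms window (5 samples × all scalp channels)
  of the −900…+200 ms epoch, a linear SVC under repeated 10-fold
  cross-validation separates two trial populations; chance is the same
  pipeline on shuffled labels; windows are tested across participants
  with Bonferroni-corrected paired t tests.  A within-condition median
  split into parts 1.1/1.2/2.1/2.2 and the six part-pair contrasts give
  per-participant decoding-group scores (mean accuracy − chance) that
  separate self-evaluation effects from time-on-task effects.
* **Group inference.**  Repeated-measures ANOVA with Greenhouse–Geisser
  correction when Mauchly's test rejects sphericity, within-subject
  Tukey HSD, and (one-tailed) Bonferroni t tests.

The synthetic generator (`errmon.synthetic`) produces epochs + trial
tables with configurable component amplitudes, a pre-response
condition-specific pattern with known onset, time-on-task drift, blinks
with known propagation, 1/f noise, and a full behavioral model — every
estimator in the package is validated by recovering those parameters.

## Worked example

```python
import errmon as em

layout = em.ExperimentLayout.default()          # 394 + 704 trials
layout.scalp_channels = em.synthetic._spread_subset(20)
layout.epoch_span_ms = (-300.0, 800.0)
truth = em.GroundTruth(seed=7, noise_sd=8.0, blink_rate=0.15,
                       cond_pattern_amp=0.0, drift_rate=0.0)

epochs, table = em.generate_experiment(truth, layout)
table = em.add_derived_columns(table)
erp = em.preprocess_erp(epochs, table)           # reref -> baseline -> EOG -> reject -> CSD
print(em.measure_components(erp, table))
```

Running `python examples/erp_components.py` (this pipeline) prints:

```
component       signaled_correct      signaled_error   nonsignaled_error
Ne_c                      -0.114              -0.437              -0.583
Pe_c_peak                  0.119               0.445               0.261
Pe_c_mean                  0.048               0.127               0.033
```

µV/cm² on the CSD scale: both error types show a clearly larger
fronto-central negativity than correct responses, and the error
positivity is largest for signaled errors — the generator's injected
structure, recovered end to end through the preprocessing chain.  The
other scripts in `examples/` demonstrate the behavioral summaries
(`behavior_summary.py`), decoding-onset recovery (`decoding_onset.py`),
and the part-split decoding-group analysis (`part_split_scores.py`).

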