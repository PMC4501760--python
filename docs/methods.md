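# Methods

This note documents the models, defaults and design choices behind
`ffrkit`, and what the synthetic-data tests do and do not establish.

## Stimulus synthesis

The [da] target is rendered from its spectro-temporal specification: a
cascade of six second-order (Klatt-style) resonators, one per formant,
excited by a 100 Hz glottal impulse train that starts at the 5 ms voice
onset time, plus a brief Hanning-windowed noise burst at onset. F1–F3
sweep linearly in Hz over the first 50 ms (400→720, 1700→1240,
2580→2500 Hz) and then hold through the 120 ms vowel; F0 and F4–F6
(3300/3750/4900 Hz) are constant. A full formant synthesizer is *not*
reproduced: only the formant tracks, F0, VOT and durations are
contractual, and the tests assert exactly those properties (sample
count, vowel periodicity, spectral-envelope maxima at the steady
formant frequencies). Formant bandwidths default to
60/90/150/200/250/300 Hz — conventional vowel-synthesis values, chosen
once; the original token's bandwidths and burst spectrum are not
published, so perceptual fidelity is out of scope. The burst is
deterministic (fixed internal seed), making the stimulus bit-stable.

The babble surrogate is six independent speech-shaped noise streams
(flat to a per-talker corner of 450–600 Hz, −12 dB/octave above) with
sinusoidal amplitude modulation at the syllabic rate (4 Hz), summed and
normalized. Each stream is synthesized in the frequency domain over the
4000 ms loop, so the loop is circularly continuous and tiles without
clicks. Real multi-talker recordings are intentionally not modelled:
only the babble's role as an asynchronous masker matters to the
pipeline, and the SNR-mixing contract is defined on RMS over the target
duration vs. the concurrent noise segment (the "+10 SNR" convention is
otherwise underdetermined).

## Synthetic cohort model

Each child has a latent preliteracy ability `a ~ N(0, 1)` that drives
both sides of the brain–behavior coupling:

* **Neural template.** Transient peaks nominally at 21/31/41/51 ms are
  Gaussian deflections (σ = 0.35 ms, amplitudes 0.45–0.5 μV) that
  dominate the transition response; first-formant harmonic amplitudes
  at 400–700 Hz (means 0.040/0.033/0.026/0.020 μV over the 20–60 ms
  transition — the tens-of-nV scale of real recordings) scale by +35%
  per SD of ability; an envelope-following 100 Hz component (0.10 μV)
  spans the voiced region; trial-level latency jitter decreases with
  ability (0.2 ms baseline, −0.05 ms per SD). Child-level timing
  variation is a single conduction delay (−0.3 ms per SD of ability
  plus 0.3 ms child noise) shared by the peaks *and* the sustained
  components, with only tiny (0.03 ms) peak-specific residuals: because
  the whole response shifts together, the transients' spectral leakage
  into the harmonic bins keeps a child-invariant phase, and planted
  harmonic amplitudes stay recoverable in rank order. (A variant with
  independent per-peak latency noise makes that leakage interfere with
  child-varying phase and destroys harmonic rank-order recovery — a
  forward-model artifact, not an estimator property.) The background's
  slope under each Gaussian pulls the composite waveform's local
  maximum off the planted latency by ≲ 0.2 ms at these amplitudes;
  this deterministic pull is part of the model and sits well inside
  the ±0.5 ms recovery tolerance. A small stimulus-artifact component
  (0.05 μV) inverts with presentation polarity and is removed by
  polarity-added averaging, as in real recordings.
* **Trials.** Each of the 4200 (preschool) or 6300 (school-age)
  presented sweeps is the template delayed by Gaussian jitter — applied
  as an exact Fourier-domain shift, valid because the template is
  band-limited far below Nyquist and zero at the epoch edges — plus a
  1/f-spectrum noise floor (per-trial SD 2 μV default, EEG-like;
  exponent configurable) and, for a random 2% of trials, a sharp
  high-amplitude excursion (50–100 μV, σ = 0.5 ms, broadband so it
  survives band-pass filtering) that the ±35 μV rejection should catch.
  The 2% rate is chosen so 4200 presented sweeps reliably retain the
  4000 needed for the final average.
* **Behavior.** True scores are affine in ability and age
  (loadings 0.8 and 0.3 on the z-scale); observed scores add
  measurement noise calibrated so that two administrations correlate at
  the test's reliability (0.9 default). Rapid-naming time is scored in
  log-seconds and loads *negatively* on ability. The optional
  learning-disability label thresholds a noisy copy of ability
  (overlap SD 0.8), so diagnostic groups overlap realistically.

Cohort defaults mirror a preschool study cohort: n = 37, age
54.4 ± 3.6 months, 57% female, scale-score IQ 10 ± 3, digitization at
16384 Hz (20 kHz for the school-age protocol). What the generator does
**not** emulate: real FFR morphology beyond the planted features,
maturational latency differences across ages, electrode/hardware
idiosyncrasies, non-stationary noise or drift. Passing recovery tests
therefore demonstrates that the pipeline's estimators are correct and
well-calibrated on signals with the stated structure — not that they
are robust to every pathology of real pediatric EEG.

## Preprocessing

Fixed stage order (logged, bit-reproducible): low-frequency boost →
band-pass → epoch/baseline → artifact rejection → polarity-added
average. Numerical choices:

* Boost: FFT multiply with a real, even gain — 0 dB at/above 100 Hz,
  +20 dB/decade below, capped at +60 dB (three decades); no windowing.
* Band-pass: second-order Butterworth (12 dB/octave per pass), 70–2000
  Hz, applied forward and backward (`sosfiltfilt`) for zero net phase;
  the zero-phase property is verified against an FFT brick-wall oracle
  (transient latency shift < 0.1 ms).
* Baseline: per-trial mean of −40–0 ms subtracted after cropping.
* Rejection: strict inequality — a trial peaking at exactly ±35.0 μV is
  retained. The threshold's boundary behaviour is undocumented in
  common acquisition packages; ties-retained is the documented choice
  here. Rejection normally runs after filtering (mirroring the
  narrative order of the offline chain); `reject_before_filter=True`
  exposes the other order for sensitivity analyses.
* Averaging: the first `final_sweeps/2` retained trials of each
  polarity in presentation order, averaged as (mean condensation +
  mean rarefaction)/2 — deterministic and order-respecting when more
  than `final_sweeps` survive.

## Neural metrics

* **Timing.** For each nominal peak the largest strict local maximum
  within ±2 ms wins, ties to the earliest sample; a window with no
  strict local maximum yields a flagged missing value. The ±2 ms window
  is a documented automation choice (peak naming conventions define
  labels, not picker bounds), and the missing-value flag replaces any
  interactive adjustment step: picking stays deterministic and
  auditable.
* **Stability.** 300 random *disjoint* polarity-balanced half-splits
  (a partition, not two independent draws — "each half comprises 50% of
  the trials" forces complementarity); Pearson r between the two
  sub-averages over 20–60 ms; the mean r is Fisher-z transformed with
  clipping at 1 − 10⁻¹² (atanh diverges at ±1). An odd polarity count
  drops the last trial of the over-represented polarity (logged).
* **Spectral.** The 20–60 ms segment gets 10 ms raised-cosine ramps at
  *both* edges (one-sided ramping would bias the offset transient),
  zero-padding to 8192 points (≤ 2 Hz resolution at 16384 Hz), and a
  single-sided amplitude spectrum compensated for the window's coherent
  gain; each harmonic amplitude is the mean over its center ± 20 Hz bin
  ("40 Hz bins" read symmetrically). No noise-floor correction is
  applied. H4–H7 and their mean are reported in μV.

## Scoring model

`PreliteracyScoreModel.fit()` runs two OLS fits (demographics;
demographics + nine neural predictors) and reports R² per block, ΔR²
(exactly their difference), the F-change statistic with
(k₂, n − k₁ − k₂ − 1) degrees of freedom, standardized β's (computed
from the fitting sample's z-scored columns), and per-predictor
tolerances (1 − R² of each predictor on the others). Rows with any
missing cell are dropped before fitting (listwise deletion, counted);
imputation would inject assumptions the data cannot support. Single
"preliminary" variants (timing-only, spectral-only, stability-only
second blocks) are the same code path with a column subset.

Transfer is frozen by construction: `predict()` uses only the raw-scale
training coefficients, carries a `refit_flag=False` provenance marker,
and gives no score (flagged) to a child missing any predictor.
Correlations are two-tailed; the optional disattenuation divides by
√reliability of the outcome only (one-sided correction — the neural
score's own reliability is not corrected), capped at 1. Cross-
validation refits on a random `n_train` subset (default 20 of 37) and
evaluates the frozen transfer on the holdout.

## Classification

With a single predictor the linear discriminant reduces to a threshold:
the pooled-variance cut between group means shifted by the log prior
ratio. Priors default to observed class frequencies (the common
statistics-package default); equal priors are exposed and the accuracy
under both is reported since the conventions can differ. Reported
statistics: resubstitution confusion matrix and percent correct, Wilks
λ = SS_within/SS_total, its χ² approximation
−(n − 1 − (p + g)/2)·ln λ with p(g−1) df, and the one-way F. The ROC is
the empirical threshold sweep (AUC = trapezoid = scaled Mann–Whitney U);
the 95% CI and the test against AUC = 0.5 use the Hanley–McNeil
standard error. The positive class defaults to "control": the score is
best interpreted as clearing children unlikely to be reading-impaired.

## Problem sizes used in the test suite

Unit tests run on desk-scale fixtures (tens of trials). The end-to-end
recovery test uses 50 synthetic children at 4000 retained sweeps with
jitter 0.25 ms and the noise level giving a per-trial SNR of −10 dB
(the stated validity domain of the recovery guarantee); stability
monotonicity runs on 400-sweep recordings over 5-point degradation
grids × 10 seeds; regression recovery uses one n = 2000 cohort plus 200
cohorts of n = 37; the permutation null uses 1000 label shuffles at
n = 55. These sizes make every estimator's behaviour measurable while
keeping the default test run fast.

## Known limitations

* The synthesizer is a resonator cascade, not a validated Klatt
  implementation; burst spectrum and bandwidths are package defaults.
* Simulated response amplitudes are plausible-scale μV, not matched to
  any particular recording system's grand averages.
* The stability statistic's null distribution is slightly negatively
  biased at finite trial counts (disjoint halves share no noise); the
  tests bound it within ±0.05 of zero rather than centering it.
* Missing peaks are excluded, never imputed; cohorts with many flagged
  peaks will lose fitting n under listwise deletion.
* No vendor EEG formats: trial matrices travel as flat binaries with
  JSON sidecars, tables as CSV/XLSX.
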