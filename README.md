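# ffrkit

Analysis toolkit for speech-evoked frequency-following responses (FFRs,
also known as cABRs) and the **consonants-in-noise score** — a frozen
hierarchical-regression prediction of preschool phonological skill from
auditory neurophysiology.

## The problem

The neural coding of consonants in background noise — how precisely,
strongly and stably the auditory system represents a stop-consonant
transition masked by multi-talker babble — tracks emergent literacy in
young children. `ffrkit` implements the full analysis chain needed to
study this relationship:

1. **Stimulus**: a 170 ms six-formant [da] synthesized at 20 kHz
   (F0 = 100 Hz, 5 ms VOT, a 50 ms /d/→/a/ formant transition with
   F1 400→720 Hz, F2 1700→1240 Hz, F3 2580→2500 Hz, steady F4–F6),
   mixed into looped six-talker babble at a chosen SNR (+10 dB default).
2. **Synthetic cohorts**: multi-trial epoched voltage matrices
   (trials × samples, μV) with a known latent-ability ground truth
   coupling neural parameters to behavioral scores, so every downstream
   stage is testable without external recordings.
3. **Preprocessing**: frequency-domain low-frequency boost (20 dB/decade
   below 100 Hz), 70–2000 Hz zero-phase Butterworth band-pass
   (12 dB/octave), epoching (−40–210 ms or −40–190 ms) with pre-stimulus
   baselining, strict ±35 μV artifact rejection, and polarity-added
   averages of 4000 (preschool) or 6000 (school-age) sweeps.
4. **Neural metrics** over the consonant-transition response (20–60 ms):
   - *timing* — latencies of transient Peaks 21/31/41/51 by windowed
     local-maximum detection;
   - *spectral* — FFT amplitudes in 40 Hz bins at the first-formant
     harmonics H4–H7 (400/500/600/700 Hz), 10 ms Hanning ramps;
   - *stability* — mean Pearson r over 300 random complementary
     half-splits of the trials, Fisher-z transformed.
5. **Scoring model**: a two-block hierarchical OLS — demographics
   (sex, age, non-verbal IQ) then the nine neural predictors — reporting
   R² per block, ΔR², the F-change test, standardized β's and
   collinearity tolerances. The fitted coefficients are frozen and
   *transferred* (never refit) to new cohorts as per-child
   consonants-in-noise scores.
6. **Downstream analyses**: Pearson correlations (with optional
   disattenuation r/√reliability), random-split cross-validation,
   single-score linear discriminant analysis (Wilks λ, χ²) and ROC/AUC
   with Hanley–McNeil confidence intervals.

## Worked example

```python
import ffrkit

# 1. synthesize the stimulus and check its periodicity
da = ffrkit.synth_da()
print(da.n_samples)                                   # 3400  (170 ms @ 20 kHz)
print(1000.0 / ffrkit.fundamental_period_ms(da.segment(60, 170)))   # 100.0 Hz

# 2. simulate a small cohort and run the pipeline end to end
from ffrkit import RunConfig, run_pipeline
cfg = RunConfig(protocol="preschool", seed=0, block2=["stability_z"],
                overrides={"cohort.n_children": 8,
                           "cohort.n_trials_per_child": 400,
                           "preproc.final_sweeps": 360})
result = run_pipeline(cfg, "scratch/demo")
print(round(result["r2_block1"], 3), round(result["r2_total"], 3))
```

Running the above prints

```
3400
100.0
0.26 0.399
```

i.e. the rendered [da] has exactly 170 ms × 20 kHz samples and a 100 Hz
fundamental in its vowel; on the 8-child demo cohort the demographic
block explains R² = 0.26 of the simulated phonological-awareness score
and adding the response-stability metric raises the total to R² = 0.399
(small-n values; they stabilize at realistic cohort sizes).

The same pipeline is scriptable from a shell:

```bash
ffr simulate --snr 10 --seed 1 --out scratch/stim
ffr run --protocol preschool --seed 0 --n-children 8 --n-sweeps 400 \
    --final-sweeps 360 --block2 stability_z --out scratch/demo
```

## Layout

```
src/ffrkit/
  stimulus.py    # [da] synthesis, babble surrogate, SNR mixing
  cohort.py      # synthetic cohorts with known ground truth
  preprocess.py  # boost -> band-pass -> epoch/baseline -> reject -> average
  metrics.py     # timing, spectral, stability metrics
  scoring.py     # hierarchical model, frozen score transfer, correlations
  classify.py    # discriminant + ROC group analyses
  tables.py      # CSV/XLSX subject tables, binary trial serialization
  pipeline.py    # protocol presets and the end-to-end runner
  cli.py         # the `ffr` command
docs/methods.md  # modelling assumptions, defaults, limitations
```
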