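"""Synthetic cohorts: per-child multi-trial FFR recordings plus behavioral tables.

A latent preliteracy ability drives both the neural response template
(peak latencies, harmonic amplitudes, trial-level jitter) and the
behavioral scores, inducing the brain-behavior couplings that the
downstream scoring model estimates.  Every generated quantity is a
deterministic function of the cohort seed, so ground truth is known
exactly and parameter recovery can be tested end to end.

The response template emulates the salient features of a speech-evoked
FFR to [da] in babble: transient peaks near 21/31/41/51 ms rendered as
Gaussian deflections, envelope-following energy at the 100 Hz fundamental,
first-formant harmonic energy at 400-700 Hz over the consonant-transition
region (20-60 ms), an optional stimulus artifact that inverts with
presentation polarity, trial-level latency jitter, a 1/f additive noise
floor, and occasional high-amplitude movement artifacts.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

#: nominal transient-peak latencies (ms) in the consonant-transition response
NOMINAL_PEAKS = (21.0, 31.0, 41.0, 51.0)

#: first-formant harmonic frequencies (Hz): H4..H7 of the 100 Hz fundamental
HARMONIC_FREQS = (400.0, 500.0, 600.0, 700.0)

BEHAVIORAL_TESTS = (
    "phonological_awareness",
    "sentence_recall",
    "rapid_naming_time",
    "reading_composite",
)


@dataclass
class ResponseTemplate:
    """Child-level generative ground truth for one FFR recording."""

    peak_latencies: np.ndarray          # ms, one per nominal peak
    peak_amplitudes: np.ndarray         # uV
    harmonic_amplitudes: np.ndarray     # uV at 400/500/600/700 Hz
    envelope_f0_amplitude: float        # uV at 100 Hz
    sample_rate: float                  # Hz
    epoch_window: tuple = (-40.0, 210.0)  # ms
    jitter_sd: float = 0.2              # ms, trial latency jitter
    artifact_component_amplitude: float = 0.05  # uV, flips with polarity
    timing_shift: float = 0.0           # ms, child-level conduction delay
                                        # shared by all response components

    def __post_init__(self):
        self.peak_latencies = np.asarray(self.peak_latencies, dtype=float)
        self.peak_amplitudes = np.asarray(self.peak_amplitudes, dtype=float)
        self.harmonic_amplitudes = np.asarray(self.harmonic_amplitudes, dtype=float)
        if np.any(np.diff(self.peak_latencies) <= 0):
            raise ValueError("peak latencies must be strictly increasing")
        if (np.any(self.peak_amplitudes < 0)
                or np.any(self.harmonic_amplitudes < 0)
                or self.envelope_f0_amplitude < 0):
            raise ValueError("amplitudes must be non-negative")
        lo, hi = self.epoch_window
        if np.any(self.peak_latencies <= lo) or np.any(self.peak_latencies >= hi):
            raise ValueError("peak latencies must lie inside the epoch window")


@dataclass
class EffectMap:
    """Linear weights linking latent ability to template and behavior.

    Positive ability means earlier peaks, larger harmonics, lower jitter,
    and better behavioral scores (rapid-naming time decreases).  Weights
    are in the units of the affected parameter per SD of latent ability.
    """

    latency_shift: float = -0.3          # ms per SD (earlier when able)
    latency_noise_sd: float = 0.3        # ms, child-level residual shared
                                         # by all peaks (conduction timing)
    per_peak_latency_noise_sd: float = 0.03  # ms, peak-specific residual
    harmonic_scale: float = 0.35         # fractional change per SD
    harmonic_noise_sd: float = 0.3       # fractional residual
    jitter_scale: float = -0.05          # ms per SD (less jitter when able)
    behavior_loading: float = 0.8        # corr(latent, true score) target
    age_loading: float = 0.3             # age contribution to true score

    def as_zero(self) -> "EffectMap":
        return EffectMap(latency_shift=0.0, latency_noise_sd=0.0,
                         per_peak_latency_noise_sd=0.0,
                         harmonic_scale=0.0, harmonic_noise_sd=0.0,
                         jitter_scale=0.0, behavior_loading=0.0,
                         age_loading=0.0)


@dataclass
class CohortSpec:
    """Study-design parameters for a simulated cohort."""

    n_children: int = 37
    age_months_mean: float = 54.41
    age_months_sd: float = 3.56
    sex_ratio_female: float = 21.0 / 37.0
    iq_mean: float = 10.0
    iq_sd: float = 3.0
    n_trials_per_child: int = 4200
    sample_rate: float = 16384.0
    epoch_window: tuple = (-40.0, 210.0)
    artifact_rate: float = 0.02
    jitter_sd: float = 0.2               # ms, population mean
    noise_sd: float = 2.0                # uV per trial (1/f floor)
    noise_exponent: float = 1.0          # spectral exponent of the floor
    effect_map: EffectMap = field(default_factory=EffectMap)
    reliability: float = 0.9             # behavioral test-retest reliability
    # transient peaks dominate the transition response; the harmonic
    # (H4-H7) spectral amplitudes of real recordings are tens of nV
    mean_peak_amplitudes: tuple = (0.50, 0.50, 0.45, 0.45)   # uV
    mean_harmonic_amplitudes: tuple = (0.040, 0.033, 0.026, 0.020)  # uV
    envelope_f0_amplitude: float = 0.10  # uV
    peak_width_ms: float = 0.35          # Gaussian sigma of transients
    assign_groups: bool = False
    group_overlap_sd: float = 0.8        # noise on the LD threshold
    group_threshold: float = -0.1        # latent cut for LD assignment
    seed: int = 0

    def validate(self) -> None:
        if self.n_trials_per_child % 2:
            raise ValueError("n_trials_per_child must be even")
        if not (0.0 <= self.artifact_rate < 1.0):
            raise ValueError("artifact_rate must be in [0, 1)")
        if not (0.0 < self.reliability <= 1.0):
            raise ValueError("reliability must be in (0, 1]")


@dataclass
class ChildRecord:
    """Demographics, behavioral scores, and simulation ground truth."""

    id: str
    age_months: float
    sex: int                         # dummy-coded: male=0, female=1
    nonverbal_iq: float
    behavioral: dict
    latent_ability: float
    group: str | None = None         # "control" / "LD" when assigned
    template: "ResponseTemplate | None" = None  # planted ground truth

    def __post_init__(self):
        if self.age_months <= 0:
            raise ValueError("age must be positive")
        if self.sex not in (0, 1):
            raise ValueError("sex is dummy-coded male=0, female=1")


class TrialSet:
    """Epoched trials x samples voltage matrix with polarity labels."""

    def __init__(self, trials: np.ndarray, polarity: np.ndarray,
                 sample_rate: float, epoch_window: tuple):
        trials = np.asarray(trials, dtype=float)
        polarity = np.asarray(polarity)
        if trials.ndim != 2:
            raise ValueError("trials must be 2-D (n_trials x n_samples)")
        if polarity.shape[0] != trials.shape[0]:
            raise ValueError("one polarity label per trial required")
        expected = int(round((epoch_window[1] - epoch_window[0])
                             * sample_rate / 1000.0))
        if trials.shape[1] != expected:
            raise ValueError(
                f"trial length {trials.shape[1]} inconsistent with epoch "
                f"window {epoch_window} at {sample_rate} Hz ({expected})"
            )
        self.trials = trials
        self.polarity = polarity
        self.sample_rate = float(sample_rate)
        self.epoch_window = (float(epoch_window[0]), float(epoch_window[1]))

    @property
    def n_trials(self) -> int:
        return self.trials.shape[0]

    @property
    def n_samples(self) -> int:
        return self.trials.shape[1]

    @property
    def times_ms(self) -> np.ndarray:
        return (self.epoch_window[0]
                + 1000.0 * np.arange(self.n_samples) / self.sample_rate)

    def mask(self, keep: np.ndarray) -> "TrialSet":
        return TrialSet(self.trials[keep], self.polarity[keep],
                        self.sample_rate, self.epoch_window)


def alternating_polarity(n_trials: int) -> np.ndarray:
    """Presentation-order polarity labels: condensation, rarefaction, ..."""
    labels = np.empty(n_trials, dtype=object)
    labels[0::2] = "condensation"
    labels[1::2] = "rarefaction"
    return labels


def generate_template(latent_ability: float, spec: CohortSpec,
                      rng: np.random.Generator | None = None) -> ResponseTemplate:
    """Map a latent ability to a child's response template.

    Template parameters are affine in ability plus seeded child-level
    noise: higher ability gives earlier peaks, larger harmonics and lower
    trial jitter (directions set by the effect map).
    """
    rng = rng or np.random.default_rng(spec.seed)
    em = spec.effect_map
    # one conduction-timing shift moves the whole response; small
    # peak-specific residuals keep the four latencies distinct predictors
    shift = (em.latency_shift * latent_ability
             + em.latency_noise_sd * rng.standard_normal())
    lat = (np.asarray(NOMINAL_PEAKS) + shift
           + em.per_peak_latency_noise_sd
           * rng.standard_normal(len(NOMINAL_PEAKS)))
    harm = np.asarray(spec.mean_harmonic_amplitudes) * (
        1.0 + em.harmonic_scale * latent_ability
        + em.harmonic_noise_sd * rng.standard_normal(len(HARMONIC_FREQS))
    )
    harm = np.clip(harm, 0.0, None)
    jitter = max(0.02, spec.jitter_sd + em.jitter_scale * latent_ability)
    return ResponseTemplate(
        peak_latencies=np.sort(lat),
        peak_amplitudes=np.asarray(spec.mean_peak_amplitudes),
        harmonic_amplitudes=harm,
        envelope_f0_amplitude=spec.envelope_f0_amplitude,
        sample_rate=spec.sample_rate,
        epoch_window=spec.epoch_window,
        jitter_sd=jitter,
        timing_shift=shift,
    )


def _edge_ramped(t_ms: np.ndarray, lo: float, hi: float,
                 ramp_ms: float = 5.0) -> np.ndarray:
    """Smooth 0/1 gate over [lo, hi] with raised-cosine edges."""
    gate = np.zeros_like(t_ms)
    inside = (t_ms >= lo) & (t_ms <= hi)
    gate[inside] = 1.0
    rise = inside & (t_ms < lo + ramp_ms)
    fall = inside & (t_ms > hi - ramp_ms)
    gate[rise] = 0.5 * (1 - np.cos(np.pi * (t_ms[rise] - lo) / ramp_ms))
    gate[fall] = 0.5 * (1 - np.cos(np.pi * (hi - t_ms[fall]) / ramp_ms))
    return gate


def render_template(template: ResponseTemplate,
                    peak_width_ms: float = 0.35) -> np.ndarray:
    """Evaluate the polarity-invariant (neural) part of the template.

    The transient deflections are Gaussians centered exactly at the
    planted latencies and phase-locked to the sustained harmonic
    background (both carry the same conduction-timing shift, as in a
    real periodic response).  The background's slope under each Gaussian
    pulls the composite waveform's local maximum off the planted value
    by a small amount — bounded by slope x sigma^2 / amplitude, about
    0.1-0.2 ms at the default amplitudes — which is part of the
    generative model's realism, not an estimator error.
    """
    lo, hi = template.epoch_window
    n = int(round((hi - lo) * template.sample_rate / 1000.0))
    t = lo + 1000.0 * np.arange(n) / template.sample_rate

    # the sustained components share the child's conduction-timing shift,
    # so their phase relation to the transient peaks is child-invariant
    s = template.timing_shift
    background = np.zeros(n)
    gate_trans = _edge_ramped(t, 20.0 + s, 60.0 + s)
    for f, amp in zip(HARMONIC_FREQS, template.harmonic_amplitudes):
        background += amp * gate_trans * np.sin(2 * np.pi * f
                                                * (t - 20.0 - s) / 1000.0)
    gate_voiced = _edge_ramped(t, 20.0 + s, min(170.0, hi))
    background += (template.envelope_f0_amplitude * gate_voiced
                   * np.sin(2 * np.pi * 100.0 * (t - s) / 1000.0))

    y = background
    for c, amp in zip(template.peak_latencies, template.peak_amplitudes):
        y = y + amp * np.exp(-0.5 * ((t - c) / peak_width_ms) ** 2)
    return y


def _one_over_f_noise(rng: np.random.Generator, shape: tuple,
                      sample_rate: float, sd: float,
                      exponent: float = 1.0) -> np.ndarray:
    """Additive noise floor with a 1/f^exponent amplitude spectrum."""
    n_trials, n_samples = shape
    freqs = np.fft.rfftfreq(n_samples, d=1.0 / sample_rate)
    weights = 1.0 / np.maximum(freqs, 1.0) ** (exponent / 2.0)
    weights[0] = 0.0
    # synthesize in the frequency domain: white Gaussian spectrum x weights
    spec = (rng.standard_normal((n_trials, freqs.size))
            + 1j * rng.standard_normal((n_trials, freqs.size))) * weights
    shaped = np.fft.irfft(spec, n=n_samples, axis=1)
    # analytic per-sample variance of the inverse transform (bins 0 and
    # Nyquist contribute their real part only)
    var = (weights[0] ** 2 + weights[-1] ** 2
           + 4.0 * np.sum(weights[1:-1] ** 2)) / n_samples**2
    shaped *= sd / np.sqrt(var)
    return shaped


def generate_trials(template: ResponseTemplate, spec: CohortSpec,
                    seed: int | np.random.Generator) -> TrialSet:
    """Render one child's multi-trial recording.

    Each trial is the template shifted by Gaussian latency jitter, plus a
    polarity-flipping stimulus-artifact component (not jittered), a 1/f
    noise floor, and — for a random ``artifact_rate`` fraction of trials —
    an injected high-amplitude excursion beyond the rejection threshold.
    """
    spec.validate()
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    n_trials = spec.n_trials_per_child
    lo, hi = template.epoch_window
    n_samples = int(round((hi - lo) * template.sample_rate / 1000.0))
    t = lo + 1000.0 * np.arange(n_samples) / template.sample_rate

    margin = 2.0  # ms of template support needed beyond the epoch edge
    jitter = template.jitter_sd * rng.standard_normal(n_trials)
    if template.jitter_sd > 0 and np.max(np.abs(jitter)) > (
            min(template.peak_latencies[0] - lo, hi - template.peak_latencies[-1])
            - margin):
        raise ValueError("latency jitter so large that peaks leave the epoch")

    # jitter applied as a Fourier-domain delay: exact for the template,
    # which is band-limited well below Nyquist and zero at the epoch edges
    base = render_template(template, spec.peak_width_ms)
    base_spec = np.fft.rfft(base)
    freqs = np.fft.rfftfreq(n_samples, d=1.0 / template.sample_rate)
    shifts = np.exp(-2j * np.pi * freqs[None, :] * jitter[:, None] / 1000.0)
    trials = np.fft.irfft(base_spec[None, :] * shifts, n=n_samples, axis=1)

    polarity = alternating_polarity(n_trials)
    if template.artifact_component_amplitude != 0.0:
        stim_art = (template.artifact_component_amplitude
                    * _edge_ramped(t, 0.0, min(170.0, hi))
                    * np.sin(2 * np.pi * 100.0 * t / 1000.0))
        sign = np.where(polarity == "condensation", 1.0, -1.0)
        trials += sign[:, None] * stim_art[None, :]

    if spec.noise_sd > 0:
        trials += _one_over_f_noise(rng, (n_trials, n_samples),
                                    template.sample_rate, spec.noise_sd,
                                    spec.noise_exponent)

    if spec.artifact_rate > 0:
        hit = rng.random(n_trials) < spec.artifact_rate
        # sharp (broadband) excursions, so they survive band-pass filtering
        for i in np.flatnonzero(hit):
            center = rng.uniform(lo + 5.0, hi - 5.0)
            amp = rng.uniform(50.0, 100.0) * rng.choice([-1.0, 1.0])
            trials[i] += amp * np.exp(-0.5 * ((t - center) / 0.5) ** 2)

    return TrialSet(trials, polarity, template.sample_rate, template.epoch_window)


def observe_score(true_score: float, true_sd: float, reliability: float,
                  rng: np.random.Generator) -> float:
    """One noisy administration of a behavioral test.

    Measurement noise is calibrated so that two independent
    administrations correlate at ``reliability`` across children.
    """
    if reliability >= 1.0:
        return float(true_score)
    err_sd = true_sd * np.sqrt((1.0 - reliability) / reliability)
    return float(true_score + err_sd * rng.standard_normal())


# behavioral score scales: (mean, SD, direction) — rapid naming is a time,
# so better ability means a *lower* value
_SCORE_SCALES = {
    "phonological_awareness": (25.0, 5.0, +1.0),
    "sentence_recall": (18.0, 4.0, +1.0),
    "rapid_naming_time": (1.75, 0.12, -1.0),   # log10 seconds
    "reading_composite": (100.0, 15.0, +1.0),
}


def iter_cohort(spec: CohortSpec, include_trials: bool = True):
    """Yield (ChildRecord, TrialSet) pairs one child at a time.

    Lazy counterpart of :func:`generate_cohort`: trial matrices are large
    (n_trials x n_samples float64), so streaming keeps memory flat for
    big cohorts.  Deterministic for a fixed spec seed.
    """
    spec.validate()
    ss = np.random.SeedSequence(spec.seed)
    child_seeds = ss.spawn(spec.n_children)
    em = spec.effect_map
    for i, cs in enumerate(child_seeds):
        rng = np.random.default_rng(cs)
        ability = float(rng.standard_normal())
        age = float(spec.age_months_mean + spec.age_months_sd * rng.standard_normal())
        sex = int(rng.random() < spec.sex_ratio_female)
        iq = float(spec.iq_mean + spec.iq_sd * rng.standard_normal())
        z_age = (age - spec.age_months_mean) / max(spec.age_months_sd, 1e-9)

        behavioral = {}
        for test, (mean, sd, direction) in _SCORE_SCALES.items():
            true_z = em.behavior_loading * ability + em.age_loading * z_age
            true = mean + direction * sd * true_z
            behavioral[test] = observe_score(true, sd, spec.reliability, rng)

        group = None
        if spec.assign_groups:
            noisy = ability + spec.group_overlap_sd * rng.standard_normal()
            group = "LD" if noisy < spec.group_threshold else "control"

        template = generate_template(ability, spec, rng)
        record = ChildRecord(id=f"child{i:03d}", age_months=age, sex=sex,
                             nonverbal_iq=iq, behavioral=behavioral,
                             latent_ability=ability, group=group,
                             template=template)
        trials = generate_trials(template, spec, rng) if include_trials else None
        yield record, trials


def generate_cohort(spec: CohortSpec, include_trials: bool = True):
    """Draw a full cohort: list of (ChildRecord, TrialSet) pairs.

    Behavioral scores are affine in latent ability and age with
    measurement noise set by the test reliability; the optional LD group
    label thresholds a noisy copy of the latent ability, so groups
    overlap.  ``include_trials=False`` skips the (expensive) trial
    rendering for behavioral-only simulations; the TrialSet slot is then
    None.  For large cohorts with trials prefer :func:`iter_cohort`.
    """
    return list(iter_cohort(spec, include_trials=include_trials))


def cohort_table(records) -> pd.DataFrame:
    """Flatten ChildRecords into a tidy table (one row per child)."""
    rows = []
    for rec in records:
        row = {"id": rec.id, "age_months": rec.age_months, "sex": rec.sex,
               "nonverbal_iq": rec.nonverbal_iq,
               "latent_ability": rec.latent_ability}
        row.update(rec.behavioral)
        if rec.group is not None:
            row["group"] = rec.group
        rows.append(row)
    return pd.DataFrame(rows)
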