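"""Synthesis of the [da] syllable, a multi-talker babble surrogate, and SNR mixing.

The target is a 170 ms voiced six-formant stop consonant [da]: a brief
release burst, a 5 ms voice onset time, a 50 ms /d/-to-/a/ formant
transition during which F1–F3 sweep linearly, and a 120 ms steady /a/
vowel.  Rendering uses a cascade of second-order resonators (one per
formant) excited by a 100 Hz glottal impulse train plus an onset noise
burst; only the spectro-temporal parameters (formant tracks, F0, VOT,
durations) are contractual, not perceptual fidelity.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field

import numpy as np

from .waveform import Waveform, n_samples_for

#: Default formant bandwidths in Hz (F1..F6) for the cascade resonators.
DEFAULT_BANDWIDTHS = (60.0, 90.0, 150.0, 200.0, 250.0, 300.0)

#: Default linear formant tracks as (start_Hz, end_Hz); steady formants
#: have start == end.  The sweep spans the consonant transition.
DEFAULT_FORMANTS = (
    (400.0, 720.0),
    (1700.0, 1240.0),
    (2580.0, 2500.0),
    (3300.0, 3300.0),
    (3750.0, 3750.0),
    (4900.0, 4900.0),
)


@dataclass
class StimulusSpec:
    """Parameters of the synthesized [da] syllable."""

    sample_rate: float = 20_000.0
    total_duration: float = 170.0      # ms
    vot: float = 5.0                   # ms, voice onset time
    transition_duration: float = 50.0  # ms, /d/ -> /a/ formant sweep
    vowel_duration: float = 120.0      # ms, steady /a/
    f0: float = 100.0                  # Hz
    formant_tracks: tuple = DEFAULT_FORMANTS
    formant_bandwidths: tuple = DEFAULT_BANDWIDTHS
    burst_duration: float = 5.0        # ms
    burst_gain: float = 0.3            # linear, relative to glottal source
    glottal_gain: float = 1.0          # linear; 0 silences voicing

    def validate(self) -> None:
        if self.transition_duration + self.vowel_duration != self.total_duration:
            raise ValueError(
                "transition_duration + vowel_duration must equal total_duration"
            )
        nyquist = self.sample_rate / 2.0
        for i, (f_start, f_end) in enumerate(self.formant_tracks, start=1):
            if max(f_start, f_end) >= nyquist:
                raise ValueError(
                    f"formant F{i} ({max(f_start, f_end):g} Hz) is at or above "
                    f"the Nyquist frequency ({nyquist:g} Hz)"
                )

    def hash(self) -> str:
        payload = json.dumps(self.__dict__, sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


@dataclass
class BabbleSpec:
    """Parameters of the six-talker babble surrogate loop."""

    n_talkers: int = 6
    n_female: int = 3
    loop_duration: float = 4000.0   # ms
    modulation_rate: float = 4.0    # Hz, syllabic amplitude modulation
    modulation_depth: float = 0.5
    seed: int = 0


def _resonator_coeffs(freq: float, bw: float, fs: float):
    """Klatt-style two-pole resonator coefficients (unity DC-free peak gain)."""
    r = np.exp(-np.pi * bw / fs)
    b = 2.0 * r * np.cos(2.0 * np.pi * freq / fs)
    c = -(r * r)
    a = 1.0 - b - c
    return a, b, c


def _cascade_filter(source: np.ndarray, freq_tracks: np.ndarray,
                    bandwidths, fs: float) -> np.ndarray:
    """Run source through cascaded time-varying resonators, one per formant."""
    y = source.copy()
    n = y.size
    for k in range(freq_tracks.shape[0]):
        a, b, c = _resonator_coeffs(freq_tracks[k], np.full(n, bandwidths[k]), fs)
        out = np.zeros(n)
        y1 = y2 = 0.0
        for i in range(n):
            out[i] = a[i] * y[i] + b[i] * y1 + c[i] * y2
            y2 = y1
            y1 = out[i]
        y = out
    return y


def synth_da(spec: StimulusSpec | None = None) -> Waveform:
    """Render the [da] syllable from its spectro-temporal specification.

    The glottal impulse train at ``f0`` starts at the voice onset time;
    F1–F3 sweep linearly over the transition then hold, F4–F6 and F0 are
    constant throughout.  The output is peak-normalized to |x| <= 1.
    """
    spec = spec or StimulusSpec()
    spec.validate()
    fs = spec.sample_rate
    n = n_samples_for(spec.total_duration, fs)
    t_ms = 1000.0 * np.arange(n) / fs

    # formant trajectories: linear sweep over [0, transition], then hold
    frac = np.clip(t_ms / spec.transition_duration, 0.0, 1.0)
    tracks = np.array([
        start + (end - start) * frac for start, end in spec.formant_tracks
    ])

    # glottal source: impulse train at f0 beginning at the voice onset time
    source = np.zeros(n)
    if spec.glottal_gain != 0.0 and spec.f0 > 0:
        period = fs / spec.f0
        start_idx = n_samples_for(spec.vot, fs)
        idx = np.round(np.arange(start_idx, n, period)).astype(int)
        source[idx[idx < n]] = spec.glottal_gain

    # release burst: brief noise transient at onset (deterministic)
    if spec.burst_gain != 0.0 and spec.burst_duration > 0:
        nb = min(n_samples_for(spec.burst_duration, fs), n)
        rng = np.random.default_rng(0xDA)
        burst = rng.standard_normal(nb) * np.hanning(nb)
        source[:nb] += spec.burst_gain * burst

    y = _cascade_filter(source, tracks, spec.formant_bandwidths, fs)

    peak = np.max(np.abs(y))
    if peak > 0:
        y = y / peak
    return Waveform(y, fs, t0=0.0, units="au")


def _speech_shaped_spectrum(freqs: np.ndarray, corner: float) -> np.ndarray:
    """Magnitude envelope: flat below the corner, -12 dB/octave above."""
    with np.errstate(divide="ignore"):
        g = 1.0 / (1.0 + (freqs / corner) ** 2)
    return g


def synth_babble(spec: BabbleSpec, sample_rate: float,
                 out_duration: float) -> Waveform:
    """Render the looped multi-talker babble surrogate.

    Each talker is an independent speech-shaped noise stream with slow
    (syllabic-rate) amplitude modulation.  The loop is built in the
    frequency domain so it is circularly continuous: tiling it produces
    no discontinuity at the seam.
    """
    if out_duration <= 0:
        raise ValueError("out_duration must be positive")
    fs = sample_rate
    n_loop = n_samples_for(spec.loop_duration, fs)
    rng = np.random.default_rng(spec.seed)
    freqs = np.fft.rfftfreq(n_loop, d=1.0 / fs)
    t = np.arange(n_loop) / fs

    # integer modulation cycles over the loop keep the seam continuous
    cycles = max(1, int(round(spec.modulation_rate * spec.loop_duration / 1000.0)))
    mod_rate = cycles * 1000.0 / spec.loop_duration

    loop = np.zeros(n_loop)
    for talker in range(spec.n_talkers):
        corner = 600.0 if talker < spec.n_female else 450.0
        mag = _speech_shaped_spectrum(freqs, corner)
        phase = rng.uniform(0, 2 * np.pi, freqs.size)
        spectrum = mag * np.exp(1j * phase)
        spectrum[0] = 0.0
        stream = np.fft.irfft(spectrum, n=n_loop)
        stream /= np.sqrt(np.mean(stream**2))
        phi = rng.uniform(0, 2 * np.pi)
        envelope = 1.0 + spec.modulation_depth * np.sin(2 * np.pi * mod_rate * t + phi)
        loop += stream * envelope
    loop /= spec.n_talkers

    n_out = n_samples_for(out_duration, fs)
    reps = int(np.ceil(n_out / n_loop))
    samples = np.tile(loop, reps)[:n_out]
    return Waveform(samples, fs, t0=0.0, units="au")


def mix_at_snr(target: Waveform, noise: Waveform, snr_db: float) -> Waveform:
    """Sum target and noise after rescaling the noise to the requested SNR.

    The SNR reference is RMS of the target over its full duration against
    RMS of the noise over the concurrent segment.
    """
    if target.sample_rate != noise.sample_rate:
        raise ValueError("target and noise sample rates differ")
    if noise.n_samples < target.n_samples:
        raise ValueError("noise must be at least as long as the target")
    rms_t = target.rms()
    seg = noise.samples[: target.n_samples]
    rms_n = float(np.sqrt(np.mean(seg**2)))
    if rms_t == 0.0:
        raise ValueError("silent target: SNR undefined")
    if rms_n == 0.0:
        raise ValueError("silent noise: SNR undefined")
    scale = rms_t / (rms_n * 10.0 ** (snr_db / 20.0))
    return Waveform(target.samples + scale * seg, target.sample_rate,
                    t0=target.t0, units=target.units)


def fundamental_period_ms(wave: Waveform, lo_hz: float = 66.0,
                          hi_hz: float = 333.0) -> float:
    """Period of the dominant periodicity via the autocorrelation maximum.

    Returns the lag (ms) of the largest non-zero-lag autocorrelation value
    within the lag range corresponding to [lo_hz, hi_hz].
    """
    x = wave.samples - np.mean(wave.samples)
    ac = np.correlate(x, x, mode="full")[x.size - 1:]
    fs = wave.sample_rate
    lag_min = max(1, int(np.floor(fs / hi_hz)))
    lag_max = min(ac.size - 1, int(np.ceil(fs / lo_hz)))
    if lag_max <= lag_min:
        raise ValueError("waveform too short for the requested lag range")
    lag = lag_min + int(np.argmax(ac[lag_min:lag_max + 1]))
    return 1000.0 * lag / fs
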