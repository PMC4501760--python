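"""Offline preprocessing of epoched FFR trials.

Fixed stage order: low-frequency boost -> zero-phase band-pass ->
epoch/baseline -> artifact rejection -> polarity combination and
averaging.  Re-running with an identical configuration and input is
bit-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .cohort import TrialSet

log = logging.getLogger(__name__)


@dataclass
class PreprocessConfig:
    """Offline preprocessing parameters.

    The defaults follow the preschool protocol: a frequency-domain
    low-frequency boost (20 dB/decade for three decades below 100 Hz,
    restoring energy attenuated by the online high-pass), a 70-2,000 Hz
    Butterworth band-pass at 12 dB/octave applied forward and backward
    (zero phase), epoching to -40-210 ms with the -40-0 ms pre-stimulus
    mean subtracted, strict +/-35 uV artifact rejection, and a
    4,000-sweep polarity-added average.
    """

    boost_corner: float = 100.0       # Hz
    boost_slope_db_per_decade: float = 20.0
    boost_decades: float = 3.0
    band: tuple = (70.0, 2000.0)      # Hz
    filter_order: int = 2             # 12 dB/octave per pass
    epoch: tuple = (-40.0, 210.0)     # ms
    baseline_window: tuple = (-40.0, 0.0)  # ms
    artifact_threshold_uv: float = 35.0
    final_sweeps: int = 4000

    def validate(self, sample_rate: float) -> None:
        nyq = sample_rate / 2.0
        if not (0.0 < self.band[0] < self.band[1] < nyq):
            raise ValueError(
                f"band {self.band} must lie inside (0, {nyq:g}) Hz"
            )
        if not (self.epoch[0] < 0.0 < self.epoch[1]):
            raise ValueError("epoch must straddle stimulus onset (0 ms)")
        if self.final_sweeps % 2:
            raise ValueError("final_sweeps must be even")
        if self.artifact_threshold_uv <= 0:
            raise ValueError("artifact threshold must be positive")

    def hash(self) -> str:
        payload = json.dumps(self.__dict__, sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


@dataclass
class AverageResponse:
    """Final polarity-added average of one recording."""

    samples: np.ndarray     # uV
    sample_rate: float
    t0: float               # ms of first sample relative to stimulus onset
    n_sweeps_included: int
    provenance: str = ""    # config hash

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float)
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("average contains non-finite samples")

    @property
    def times_ms(self) -> np.ndarray:
        return self.t0 + 1000.0 * np.arange(self.samples.size) / self.sample_rate

    def window(self, start_ms: float, end_ms: float) -> np.ndarray:
        i0 = int(round((start_ms - self.t0) * self.sample_rate / 1000.0))
        i1 = int(round((end_ms - self.t0) * self.sample_rate / 1000.0))
        if i0 < 0 or i1 > self.samples.size:
            raise ValueError("window outside epoch")
        return self.samples[i0:i1]


def boost_gain(freqs: np.ndarray, cfg: PreprocessConfig) -> np.ndarray:
    """Linear gain of the low-frequency boost as a function of frequency.

    Unity at and above the corner; below it the gain rises at the stated
    dB/decade slope, capped after the stated number of decades (60 dB at
    and below 0.1 Hz for the defaults).
    """
    freqs = np.asarray(freqs, dtype=float)
    cap_db = cfg.boost_slope_db_per_decade * cfg.boost_decades
    with np.errstate(divide="ignore"):
        db = cfg.boost_slope_db_per_decade * np.log10(cfg.boost_corner / freqs)
    db = np.clip(db, 0.0, cap_db)
    db = np.where(freqs == 0.0, cap_db, db)
    return 10.0 ** (db / 20.0)


def low_freq_boost(trials: TrialSet, cfg: PreprocessConfig) -> TrialSet:
    """Frequency-domain amplification below the boost corner.

    Implemented as an FFT multiply with a real, even gain function
    (applied symmetrically to conjugate frequencies), so the output is
    real-valued and phase is untouched.
    """
    n = trials.n_samples
    freqs = np.fft.rfftfreq(n, d=1.0 / trials.sample_rate)
    gain = boost_gain(freqs, cfg)
    spec = np.fft.rfft(trials.trials, axis=1)
    out = np.fft.irfft(spec * gain, n=n, axis=1)
    return TrialSet(out, trials.polarity, trials.sample_rate, trials.epoch_window)


def bandpass(trials: TrialSet, cfg: PreprocessConfig) -> TrialSet:
    """Zero-phase Butterworth band-pass (forward-backward application)."""
    cfg.validate(trials.sample_rate)
    sos = signal.butter(cfg.filter_order, cfg.band, btype="bandpass",
                        fs=trials.sample_rate, output="sos")
    out = signal.sosfiltfilt(sos, trials.trials, axis=1)
    return TrialSet(out, trials.polarity, trials.sample_rate, trials.epoch_window)


def epoch_baseline(trials: TrialSet, cfg: PreprocessConfig) -> TrialSet:
    """Crop each trial to the epoch and subtract its pre-stimulus mean."""
    lo, hi = trials.epoch_window
    fs = trials.sample_rate
    i0 = int(round((cfg.epoch[0] - lo) * fs / 1000.0))
    i1 = int(round((cfg.epoch[1] - lo) * fs / 1000.0))
    if i0 < 0 or i1 > trials.n_samples:
        raise ValueError(
            f"epoch {cfg.epoch} ms outside trial extent {trials.epoch_window}"
        )
    cropped = trials.trials[:, i0:i1]
    b0 = int(round((cfg.baseline_window[0] - cfg.epoch[0]) * fs / 1000.0))
    b1 = int(round((cfg.baseline_window[1] - cfg.epoch[0]) * fs / 1000.0))
    if b1 <= b0:
        raise ValueError("baseline window is empty")
    baseline = cropped[:, b0:b1].mean(axis=1, keepdims=True)
    return TrialSet(cropped - baseline, trials.polarity, fs, cfg.epoch)


def reject_artifacts(trials: TrialSet, cfg: PreprocessConfig):
    """Drop every trial with any sample strictly beyond the threshold.

    Returns (clean TrialSet, number rejected).  Rejection is a strict
    inequality: a trial peaking at exactly +/-35.0 uV is retained.
    """
    bad = np.any(np.abs(trials.trials) > cfg.artifact_threshold_uv, axis=1)
    n_bad = int(bad.sum())
    if n_bad == trials.n_trials:
        raise ValueError(
            f"all trials exceeded +/-{cfg.artifact_threshold_uv:g} uV"
        )
    log.info("artifact rejection: removed %d of %d trials", n_bad, trials.n_trials)
    return trials.mask(~bad), n_bad


def combine_polarities_and_average(trials: TrialSet,
                                   cfg: PreprocessConfig) -> AverageResponse:
    """Polarity-added final average over the first retained sweeps.

    Takes final_sweeps/2 retained trials of each polarity in presentation
    order and averages the two single-polarity means, cancelling any
    component that inverts with stimulus polarity.
    """
    half = cfg.final_sweeps // 2
    cond = trials.polarity == "condensation"
    rare = trials.polarity == "rarefaction"
    n_c, n_r = int(cond.sum()), int(rare.sum())
    if n_c < half or n_r < half:
        raise ValueError(
            f"insufficient balanced trials for a {cfg.final_sweeps}-sweep "
            f"average: need {half} per polarity, have condensation={n_c}, "
            f"rarefaction={n_r}"
        )
    mean_c = trials.trials[np.flatnonzero(cond)[:half]].mean(axis=0)
    mean_r = trials.trials[np.flatnonzero(rare)[:half]].mean(axis=0)
    avg = 0.5 * (mean_c + mean_r)
    return AverageResponse(avg, trials.sample_rate, trials.epoch_window[0],
                           cfg.final_sweeps, provenance=cfg.hash())


def preprocess(trials: TrialSet, cfg: PreprocessConfig | None = None,
               reject_before_filter: bool = False):
    """Run the full chain; returns (clean TrialSet, AverageResponse).

    The clean TrialSet (boosted, filtered, baselined, artifact-free) is
    what the stability metric consumes; the AverageResponse feeds the
    timing and spectral metrics.  The default stage order is
    boost -> bandpass -> epoch/baseline -> reject -> combine;
    ``reject_before_filter`` screens artifacts on the raw epoched trials
    instead, for sensitivity analyses of the rejection order.
    """
    cfg = cfg or PreprocessConfig()
    cfg.validate(trials.sample_rate)
    if reject_before_filter:
        x, n_rejected = reject_artifacts(epoch_baseline(trials, cfg), cfg)
        x = epoch_baseline(bandpass(low_freq_boost(x, cfg), cfg), cfg)
    else:
        x = low_freq_boost(trials, cfg)
        x = bandpass(x, cfg)
        x = epoch_baseline(x, cfg)
        x, n_rejected = reject_artifacts(x, cfg)
    avg = combine_polarities_and_average(x, cfg)
    log.info("preprocess: %d sweeps in, %d rejected, %d averaged",
             trials.n_trials, n_rejected, avg.n_sweeps_included)
    return x, avg
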