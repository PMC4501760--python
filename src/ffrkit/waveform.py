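"""Light-weight sampled-signal container shared by the stimulus and response code."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.io import wavfile


@dataclass
class Waveform:
    """A sampled acoustic or neural signal.

    Parameters
    ----------
    samples : ndarray
        Amplitude sequence (arbitrary acoustic units, or microvolts for
        neural signals).
    sample_rate : float
        Sampling rate in Hz. Must be positive.
    t0 : float
        Time of the first sample in ms, relative to stimulus onset.
    units : str
        Label for the amplitude units.
    """

    samples: np.ndarray
    sample_rate: float
    t0: float = 0.0
    units: str = "au"

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("waveform contains non-finite samples")

    @property
    def n_samples(self) -> int:
        return self.samples.shape[-1]

    @property
    def duration_ms(self) -> float:
        return 1000.0 * self.n_samples / self.sample_rate

    @property
    def times_ms(self) -> np.ndarray:
        """Sample times in ms relative to stimulus onset."""
        return self.t0 + 1000.0 * np.arange(self.n_samples) / self.sample_rate

    def rms(self) -> float:
        return float(np.sqrt(np.mean(self.samples**2)))

    def segment(self, start_ms: float, end_ms: float) -> "Waveform":
        """Return the [start_ms, end_ms) portion (times relative to onset)."""
        i0 = int(round((start_ms - self.t0) * self.sample_rate / 1000.0))
        i1 = int(round((end_ms - self.t0) * self.sample_rate / 1000.0))
        if i0 < 0 or i1 > self.n_samples or i1 <= i0:
            raise ValueError(
                f"segment [{start_ms}, {end_ms}) ms outside waveform extent"
            )
        return Waveform(self.samples[i0:i1], self.sample_rate, start_ms, self.units)

    def to_wav(self, path) -> None:
        """Write as a 32-bit float PCM WAV file."""
        wavfile.write(path, int(round(self.sample_rate)),
                      self.samples.astype(np.float32))


def n_samples_for(duration_ms: float, sample_rate: float) -> int:
    return int(round(duration_ms * sample_rate / 1000.0))
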