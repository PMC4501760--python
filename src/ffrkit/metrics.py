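"""The three neural-coding measure families of the consonant-transition FFR.

* Neural timing: latencies of the transient peaks near 21/31/41/51 ms,
  picked as the largest strict local maximum in a window around each
  nominal latency (automated stand-in for interactive peak editing; a
  window with no local maximum yields a flagged missing value).
* Neural stability: mean Pearson correlation between many random
  complementary half-splits of the retained trials, restricted to the
  consonant-transition window (20-60 ms), Fisher-z transformed.
* Spectral features: Hanning-ramped FFT amplitudes in 40 Hz bins centered
  on the first-formant harmonics (400/500/600/700 Hz), plus their mean.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal.windows import tukey

from .cohort import TrialSet
from .preprocess import AverageResponse

#: column order of the nine neural predictors, matching the score model
METRIC_COLUMNS = [
    "peak_21", "peak_31", "peak_41", "peak_51",
    "h4", "h5", "h6", "h7",
    "stability_z",
]

FISHER_EPS = 1e-12


@dataclass
class PeakConfig:
    nominal_latencies: tuple = (21.0, 31.0, 41.0, 51.0)  # ms
    search_halfwidth: float = 2.0    # ms
    analysis_window: tuple = (20.0, 60.0)  # ms


@dataclass
class StabilityConfig:
    n_pairs: int = 300
    window: tuple = (20.0, 60.0)     # ms
    seed: int = 0


@dataclass
class SpectralConfig:
    window: tuple = (20.0, 60.0)     # ms
    ramp_ms: float = 10.0            # Hanning ramp at each window edge
    harmonics: tuple = (400.0, 500.0, 600.0, 700.0)  # Hz
    bin_halfwidth: float = 20.0      # Hz; "40 Hz bins" = center +/- 20
    fft_length: int = 8192


@dataclass
class NeuralMetrics:
    """The nine neural predictors for one child (NaN marks a missing peak)."""

    peak_latencies: dict            # nominal (ms) -> picked latency or NaN
    h4: float
    h5: float
    h6: float
    h7: float
    f1_mean_amplitude: float
    stability_r: float
    stability_z: float
    missing_peaks: tuple = ()
    provenance: str = ""

    def as_row(self) -> dict:
        row = {f"peak_{int(k)}": v for k, v in self.peak_latencies.items()}
        row.update(h4=self.h4, h5=self.h5, h6=self.h6, h7=self.h7,
                   stability_z=self.stability_z)
        return row


def detect_peaks(avg: AverageResponse, cfg: PeakConfig | None = None):
    """Pick the transient-peak latencies by local-maximum detection.

    For each nominal latency, the largest strict local maximum (a sample
    exceeding both neighbours) within nominal +/- search_halfwidth wins;
    ties break to the earliest.  A window with no strict local maximum
    gives NaN and the nominal latency is flagged.

    Returns (dict nominal -> latency_ms, tuple of flagged nominals).
    """
    cfg = cfg or PeakConfig()
    t = avg.times_ms
    x = avg.samples
    latencies: dict = {}
    flagged = []
    for nominal in cfg.nominal_latencies:
        in_win = (t >= nominal - cfg.search_halfwidth) & \
                 (t <= nominal + cfg.search_halfwidth)
        idx = np.flatnonzero(in_win)
        # strict local maxima (interior samples only)
        cand = [i for i in idx
                if 0 < i < x.size - 1 and x[i] > x[i - 1] and x[i] > x[i + 1]]
        if not cand:
            latencies[nominal] = math.nan
            flagged.append(nominal)
            continue
        heights = np.array([x[i] for i in cand])
        best = cand[int(np.argmax(heights))]  # argmax returns first max: earliest tie
        latencies[nominal] = float(t[best])
    return latencies, tuple(flagged)


def _balanced_half_masks(rng: np.random.Generator, polarity: np.ndarray,
                         n_pairs: int) -> np.ndarray:
    """Boolean (n_pairs, n_trials) masks selecting polarity-balanced halves."""
    n = polarity.size
    masks = np.zeros((n_pairs, n), dtype=bool)
    for lab in ("condensation", "rarefaction"):
        idx = np.flatnonzero(polarity == lab)
        half = idx.size // 2
        for p in range(n_pairs):
            pick = rng.permutation(idx)[:half]
            masks[p, pick] = True
    return masks


def _rowwise_pearson(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    a = a - a.mean(axis=1, keepdims=True)
    b = b - b.mean(axis=1, keepdims=True)
    num = np.sum(a * b, axis=1)
    den = np.sqrt(np.sum(a * a, axis=1) * np.sum(b * b, axis=1))
    return num / den


def stability(trials: TrialSet, cfg: StabilityConfig | None = None):
    """Trial-by-trial response stability over the consonant transition.

    Repeats ``n_pairs`` times: randomly partition the retained trials
    into two disjoint polarity-balanced halves, average each half with
    polarity addition, and correlate the two sub-averages over the
    20-60 ms window.  Returns (mean r, Fisher z of the mean r).
    """
    cfg = cfg or StabilityConfig()
    if trials.n_trials < 4:
        raise ValueError("stability requires at least 4 retained trials")
    rng = np.random.default_rng(cfg.seed)

    pol = trials.polarity
    keep = np.ones(trials.n_trials, dtype=bool)
    # drop the last trial of the over-represented polarity if counts are odd
    for lab in ("condensation", "rarefaction"):
        idx = np.flatnonzero(pol == lab)
        if idx.size % 2:
            keep[idx[-1]] = False
    trials = trials.mask(keep) if not keep.all() else trials
    pol = trials.polarity

    fs = trials.sample_rate
    lo = trials.epoch_window[0]
    i0 = int(round((cfg.window[0] - lo) * fs / 1000.0))
    i1 = int(round((cfg.window[1] - lo) * fs / 1000.0))
    w = trials.trials[:, i0:i1]

    masks = _balanced_half_masks(rng, pol, cfg.n_pairs)
    n_half = masks[0].sum()
    total = w.sum(axis=0)
    half1 = masks.astype(float) @ w / n_half
    half2 = (total[None, :] - half1 * n_half) / (trials.n_trials - n_half)
    r_vals = _rowwise_pearson(half1, half2)
    r_mean = float(np.mean(r_vals))
    z = float(np.arctanh(np.clip(r_mean, -1.0 + FISHER_EPS, 1.0 - FISHER_EPS)))
    return r_mean, z


def spectral_amplitudes(avg: AverageResponse, cfg: SpectralConfig | None = None):
    """First-formant harmonic amplitudes from the 20-60 ms response FFT.

    The windowed segment gets 10 ms raised-cosine (Hanning) ramps at both
    edges, is zero-padded, and its single-sided amplitude spectrum (in uV,
    compensated for the window's coherent gain) is averaged within the
    40 Hz bin around each harmonic.

    Returns (h4, h5, h6, h7, mean of the four).
    """
    cfg = cfg or SpectralConfig()
    seg = avg.window(*cfg.window)
    n = seg.size
    if cfg.fft_length < n:
        raise ValueError("fft_length shorter than the analysis segment")
    ramp_samples = int(round(cfg.ramp_ms * avg.sample_rate / 1000.0))
    if 2 * ramp_samples > n:
        raise ValueError("ramps longer than the analysis segment")
    win = tukey(n, alpha=2.0 * ramp_samples / n)
    spec = np.fft.rfft(seg * win, n=cfg.fft_length)
    amp = 2.0 * np.abs(spec) / win.sum()
    freqs = np.fft.rfftfreq(cfg.fft_length, d=1.0 / avg.sample_rate)

    out = []
    for center in cfg.harmonics:
        in_bin = (freqs >= center - cfg.bin_halfwidth) & \
                 (freqs <= center + cfg.bin_halfwidth)
        out.append(float(np.mean(amp[in_bin])))
    return (*out, float(np.mean(out)))


def compute_metrics(avg: AverageResponse, trials: TrialSet,
                    peak_cfg: PeakConfig | None = None,
                    stab_cfg: StabilityConfig | None = None,
                    spec_cfg: SpectralConfig | None = None) -> NeuralMetrics:
    """Bundle the nine neural predictors for one child.

    By construction this takes no behavioral inputs: the neural metrics
    are computed blind to any behavioral data.
    """
    peak_cfg = peak_cfg or PeakConfig()
    stab_cfg = stab_cfg or StabilityConfig()
    spec_cfg = spec_cfg or SpectralConfig()
    latencies, flagged = detect_peaks(avg, peak_cfg)
    r, z = stability(trials, stab_cfg)
    h4, h5, h6, h7, f1 = spectral_amplitudes(avg, spec_cfg)
    return NeuralMetrics(peak_latencies=latencies, h4=h4, h5=h5, h6=h6, h7=h7,
                         f1_mean_amplitude=f1, stability_r=r, stability_z=z,
                         missing_peaks=flagged, provenance=avg.provenance)


def metrics_table(metrics_by_child: dict) -> pd.DataFrame:
    """One row per child, columns exactly the nine predictor names."""
    rows = {cid: m.as_row() for cid, m in metrics_by_child.items()}
    df = pd.DataFrame.from_dict(rows, orient="index")[METRIC_COLUMNS]
    df.index.name = "id"
    return df


def mean_intermetric_correlation(df: pd.DataFrame) -> float:
    """Mean pairwise |r| among the nine neural metrics across children."""
    corr = df[METRIC_COLUMNS].corr().to_numpy()
    iu = np.triu_indices_from(corr, k=1)
    return float(np.nanmean(np.abs(corr[iu])))
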