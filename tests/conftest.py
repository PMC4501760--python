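import numpy as np
import pytest

from ffrkit.cohort import TrialSet, alternating_polarity


def make_trialset(trials, sample_rate=16384.0, epoch=None, polarity=None):
    """TrialSet from a raw matrix with alternating polarity labels.

    Without an explicit epoch the window starts at -40 ms and spans
    however many samples the matrix has.
    """
    trials = np.asarray(trials, dtype=float)
    if epoch is None:
        epoch = (-40.0, -40.0 + 1000.0 * trials.shape[1] / sample_rate)
    if polarity is None:
        polarity = alternating_polarity(trials.shape[0])
    return TrialSet(trials, polarity, sample_rate, epoch)


def sine_trials(freq_hz, amp=1.0, n_trials=4, sample_rate=16384.0,
                epoch=(-100.0, 400.0)):
    """Identical pure-sinusoid trials (useful for filter-gain checks)."""
    n = int(round((epoch[1] - epoch[0]) * sample_rate / 1000.0))
    t = np.arange(n) / sample_rate
    x = amp * np.sin(2 * np.pi * freq_hz * t)
    return make_trialset(np.tile(x, (n_trials, 1)), sample_rate, epoch)


@pytest.fixture(scope="session")
def default_da():
    """The default synthesized [da] (shared: synthesis is deterministic)."""
    from ffrkit.stimulus import synth_da
    return synth_da()
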