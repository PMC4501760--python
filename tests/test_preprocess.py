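"""Preprocessing chain: boost gain, zero-phase filtering, epoching, rejection."""

import numpy as np
import pytest
from scipy import signal

from conftest import make_trialset, sine_trials
from ffrkit.cohort import alternating_polarity
from ffrkit.preprocess import (PreprocessConfig, bandpass, boost_gain,
                               combine_polarities_and_average, epoch_baseline,
                               low_freq_boost, preprocess, reject_artifacts)

CFG = PreprocessConfig()


def sine_amplitude(x):
    return np.sqrt(2) * np.std(x)


class TestLowFreqBoost:
    def test_one_decade_below_corner_plus_20_db(self):
        ts = sine_trials(10.0, amp=1.0)   # 500 ms window: integer cycles
        out = low_freq_boost(ts, CFG)
        assert sine_amplitude(out.trials[0]) == pytest.approx(10.0, rel=0.01)

    def test_above_corner_unity_gain(self):
        ts = sine_trials(1000.0, amp=1.0)
        out = low_freq_boost(ts, CFG)
        assert sine_amplitude(out.trials[0]) == pytest.approx(1.0, rel=1e-3)

    def test_gain_function_matches_piecewise_closed_form(self):
        # oracle: gain in dB is min(20*log10(100/f), 60), clipped at 0
        freqs = np.concatenate([[0.0], np.logspace(-3, 3.9, 500)])
        gain = boost_gain(freqs, CFG)
        with np.errstate(divide="ignore"):
            expected_db = np.clip(20.0 * np.log10(100.0 / freqs), 0.0, 60.0)
        expected_db[freqs == 0.0] = 60.0
        np.testing.assert_allclose(20 * np.log10(gain), expected_db, atol=1e-9)
        # 0.01 Hz sits at the 60 dB cap, not 80 dB
        assert boost_gain(np.array([0.01]), CFG)[0] == pytest.approx(1000.0)

    def test_output_real_valued_and_bins_above_corner_untouched(self):
        rng = np.random.default_rng(0)
        ts = make_trialset(rng.standard_normal((3, 4096)))
        out = low_freq_boost(ts, CFG)
        assert np.isrealobj(out.trials)
        freqs = np.fft.rfftfreq(4096, 1 / ts.sample_rate)
        above = freqs >= 100.0
        np.testing.assert_allclose(np.fft.rfft(out.trials, axis=1)[:, above],
                                   np.fft.rfft(ts.trials, axis=1)[:, above],
                                   atol=1e-9)


class TestBandpass:
    def test_dc_removed(self):
        ts = make_trialset(np.full((2, 4096), 5.0))
        out = bandpass(ts, CFG)
        assert np.abs(out.trials.mean()) < 1e-6

    def test_midband_preserved_zero_phase(self):
        ts = sine_trials(500.0, amp=1.0)
        out = bandpass(ts, CFG)
        mid = slice(1000, -1000)   # avoid edge transients
        assert sine_amplitude(out.trials[0][mid]) == pytest.approx(1.0, rel=0.05)
        xc = signal.correlate(out.trials[0][mid], ts.trials[0][mid], "full")
        lag = np.argmax(xc) - (len(ts.trials[0][mid]) - 1)
        assert lag == 0

    def test_stopband_attenuation_matches_butterworth_form(self):
        # two octaves below the 70 Hz edge, measured vs analytic |H|^2
        freq = 17.5
        ts = sine_trials(freq, amp=1.0, epoch=(-1000.0, 1000.0))
        out = bandpass(ts, CFG)
        mid = slice(8000, -8000)
        measured = sine_amplitude(out.trials[0][mid])
        sos = signal.butter(CFG.filter_order, CFG.band, "bandpass",
                            fs=ts.sample_rate, output="sos")
        _, h = signal.sosfreqz(sos, worN=[freq], fs=ts.sample_rate)
        analytic = np.abs(h[0]) ** 2     # forward + backward pass
        assert measured > 0
        assert abs(20 * np.log10(measured) - 20 * np.log10(analytic)) < 1.0

    def test_band_edge_at_nyquist_rejected(self):
        ts = sine_trials(100.0, sample_rate=3000.0, epoch=(0.0, 500.0))
        with pytest.raises(ValueError):
            bandpass(ts, PreprocessConfig(band=(70.0, 2000.0)))


class TestEpochBaseline:
    def test_constant_trial_zeroed(self):
        ts = make_trialset(np.full((2, 4506), 3.0), epoch=(-50.0, 225.0))
        out = epoch_baseline(ts, CFG)
        assert out.epoch_window == (-40.0, 210.0)
        np.testing.assert_allclose(out.trials, 0.0, atol=1e-12)

    def test_zero_prestim_mean_identity(self):
        fs = 16384.0
        n = 4096
        n_pre = int(round(40.0 / 1000.0 * fs))   # samples in -40-0 ms
        rng = np.random.default_rng(8)
        x = rng.standard_normal(n)
        x -= x[:n_pre].mean()
        ts = make_trialset(np.tile(x, (2, 1)))
        out = epoch_baseline(ts, CFG)
        np.testing.assert_allclose(out.trials[0], x, atol=1e-12)

    def test_random_trials_baseline_mean_zero(self):
        rng = np.random.default_rng(3)
        ts = make_trialset(rng.standard_normal((20, 4096)))
        out = epoch_baseline(ts, CFG)
        n_pre = int(round(40.0 / 1000.0 * ts.sample_rate))
        pre = out.trials[:, :n_pre]
        assert np.all(np.abs(pre.mean(axis=1)) < 1e-9)

    def test_empty_baseline_rejected(self):
        ts = make_trialset(np.zeros((2, 4096)))
        bad = PreprocessConfig(baseline_window=(-40.0, -40.0))
        with pytest.raises(ValueError, match="baseline"):
            epoch_baseline(ts, bad)


class TestRejectArtifacts:
    def test_single_excursion_removed(self):
        trials = np.zeros((4, 4096))
        trials[2, 100] = 40.0
        clean, n_bad = reject_artifacts(make_trialset(trials), CFG)
        assert n_bad == 1
        assert clean.n_trials == 3

    def test_exact_threshold_retained(self):
        trials = np.zeros((2, 4096))
        trials[0, 10] = 35.0
        trials[1, 10] = -35.0
        clean, n_bad = reject_artifacts(make_trialset(trials), CFG)
        assert n_bad == 0

    def test_exactly_planted_trials_removed(self):
        rng = np.random.default_rng(9)
        trials = rng.standard_normal((50, 1024))
        planted = [3, 17, 41]
        for i in planted:
            trials[i, rng.integers(1024)] = 80.0
        ts = make_trialset(trials)
        clean, n_bad = reject_artifacts(ts, CFG)
        assert n_bad == len(planted)
        kept = np.delete(np.arange(50), planted)
        np.testing.assert_array_equal(clean.trials, trials[kept])

    def test_all_rejected_names_threshold(self):
        ts = make_trialset(np.full((3, 1024), 100.0))
        with pytest.raises(ValueError, match="35"):
            reject_artifacts(ts, CFG)


class TestCombineAndAverage:
    def test_sign_inverting_component_cancels(self):
        n = 4096
        x = np.sin(2 * np.pi * np.arange(n) / 64)
        trials = np.array([x, -x] * 2000)
        avg = combine_polarities_and_average(make_trialset(trials), CFG)
        np.testing.assert_allclose(avg.samples, 0.0, atol=1e-12)
        assert avg.n_sweeps_included == 4000

    def test_sign_invariant_component_preserved(self):
        n = 4096
        x = 0.5 * np.sin(2 * np.pi * 100 * np.arange(n) / 16384.0)
        trials = np.tile(x, (4000, 1))
        avg = combine_polarities_and_average(make_trialset(trials), CFG)
        np.testing.assert_allclose(avg.samples, x, atol=1e-12)

    def test_selects_first_retained_per_polarity(self):
        trials = np.arange(8)[:, None] * np.ones((8, 1024))
        cfg = PreprocessConfig(final_sweeps=4)
        avg = combine_polarities_and_average(make_trialset(trials), cfg)
        # condensation trials 0,2 and rarefaction 1,3 -> mean 1.5
        np.testing.assert_allclose(avg.samples, 1.5)

    def test_insufficient_balanced_trials_reports_deficit(self):
        ts = make_trialset(np.zeros((100, 1024)))
        with pytest.raises(ValueError, match="condensation"):
            combine_polarities_and_average(ts, CFG)


class TestFullChain:
    def test_rerun_bit_identical(self):
        rng = np.random.default_rng(1)
        trials = rng.standard_normal((40, 4096))
        cfg = PreprocessConfig(final_sweeps=20)
        _, avg1 = preprocess(make_trialset(trials), cfg)
        _, avg2 = preprocess(make_trialset(trials.copy()), cfg)
        np.testing.assert_array_equal(avg1.samples, avg2.samples)
        assert avg1.provenance == avg2.provenance

    def test_zero_phase_latency_vs_fft_mask_oracle(self):
        # a dominant transient's argmax moves < 0.1 ms relative to an
        # ideal (zero-phase by construction) FFT brick-wall filter
        fs = 16384.0
        n = 4096
        t = -40.0 + 1000.0 * np.arange(n) / fs
        x = np.exp(-0.5 * ((t - 31.0) / 0.8) ** 2)
        ts = make_trialset(np.tile(x, (4, 1)))
        out = bandpass(ts, CFG)

        freqs = np.fft.rfftfreq(n, 1 / fs)
        mask = (freqs >= CFG.band[0]) & (freqs <= CFG.band[1])
        oracle = np.fft.irfft(np.fft.rfft(x) * mask, n=n)

        win = (t >= 20.0) & (t <= 60.0)
        lat_filt = t[win][np.argmax(out.trials[0][win])]
        lat_oracle = t[win][np.argmax(oracle[win])]
        assert abs(lat_filt - lat_oracle) < 0.1

    def test_reject_before_filter_order_exposed(self):
        rng = np.random.default_rng(2)
        trials = rng.standard_normal((40, 4096))
        trials[5, 500] = 100.0   # raw-domain spike artifact
        cfg = PreprocessConfig(final_sweeps=20)
        clean, avg = preprocess(make_trialset(trials), cfg,
                                reject_before_filter=True)
        assert clean.n_trials == 39
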