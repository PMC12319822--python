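"""Multitaper time-frequency analysis and band-peak extraction."""

import numpy as np
import pandas as pd
import pytest

from gammaflow import spectral
from gammaflow.errors import ConfigError, InputError, NumericalError
from gammaflow.spectral import TfPower

FS = 500.0


def epochs_of(wave, n_trials=1, n_locs=1):
    return np.tile(wave, (n_trials, n_locs, 1))


def marks_for(tf, mt=0.5):
    n = tf.n_trials
    return pd.DataFrame({
        "trial": np.arange(n), "go_sample": np.zeros(n, int),
        "onset_s": np.zeros(n), "offset_s": np.full(n, mt),
        "rt_s": np.zeros(n), "mt_s": np.full(n, mt),
        "envelope_peak": np.ones(n), "detected": [True] * n,
    })


class TestMultitaper:
    def test_pure_tone_peaks_at_its_frequency_in_every_window(self):
        t = np.arange(int(4 * FS)) / FS
        tf = spectral.multitaper_tf(epochs_of(np.sin(2 * np.pi * 40 * t)),
                                    FS, t_start=-2.0, fmin=30, fmax=60)
        assert np.allclose(tf.freqs % 1.0, 0.0)
        assert tf.times[0] == pytest.approx(-1.2)
        peak_f = tf.freqs[np.argmax(tf.power[0, 0], axis=0)]
        assert np.all(peak_f == 40.0)

    def test_burst_power_localised_in_time(self):
        t = np.arange(int(4 * FS)) / FS - 2.0
        wave = np.sin(2 * np.pi * 40 * t) * ((t >= 0) & (t < 0.5))
        tf = spectral.multitaper_tf(epochs_of(wave), FS, t_start=-2.0,
                                    fmin=35, fmax=45)
        fi = int(np.argmax(np.isclose(tf.freqs, 40.0)))
        tc = tf.power[0, 0, fi]
        t_max = tf.times[np.argmax(tc)]
        # burst centre 0.25 s; max window centre within half a window
        assert -0.8 + 0.25 <= t_max <= 0.8 + 0.25

    def test_white_noise_spectrum_flat_within_3db(self):
        g = np.random.default_rng(8)
        epochs = g.standard_normal((40, 1, int(4 * FS)))
        tf = spectral.multitaper_tf(epochs, FS, t_start=-2.0, fmin=20, fmax=80)
        spec = tf.power.mean(axis=(0, 1, 3))
        assert 10 * np.log10(spec.max() / spec.min()) < 3.0

    def test_too_small_bandwidth_rejected(self):
        with pytest.raises(ConfigError):
            spectral.multitaper_tf(np.zeros((1, 1, int(4 * FS))), FS,
                                   t_start=-2.0, fmin=30, fmax=60,
                                   half_bandwidth=0.1)

    def test_epoch_shorter_than_window_rejected(self):
        with pytest.raises(InputError):
            spectral.multitaper_tf(np.zeros((1, 1, 100)), FS, t_start=0.0,
                                   fmin=30, fmax=60)


def flat_tf(value=1.0, n_trials=2, n_locs=3):
    freqs = np.arange(30.0, 61.0)
    times = np.arange(-1.2, 1.21, 0.2)
    power = np.full((n_trials, n_locs, freqs.size, times.size), value)
    return TfPower(power=power, freqs=freqs, times=np.round(times, 10))


class TestBaselineCorrect:
    def test_stationary_power_corrects_to_zero(self):
        out = spectral.baseline_correct(flat_tf(2.5), (-1.0, -0.5))
        assert np.allclose(out.power, 0.0)
        assert out.kind == "relative"

    def test_power_doubling_gives_relative_one(self):
        tf = flat_tf(1.0)
        sel = tf.times >= 0
        tf.power[..., sel] = 2.0
        out = spectral.baseline_correct(tf, (-1.0, -0.5))
        assert np.allclose(out.power[..., sel], 1.0)

    def test_trial_mean_over_baseline_bins_is_zero(self):
        g = np.random.default_rng(3)
        tf = flat_tf(1.0, n_trials=6)
        tf.power *= g.uniform(0.5, 1.5, tf.power.shape)
        out = spectral.baseline_correct(tf, (-1.0, -0.5))
        sel = (out.times >= -1.0) & (out.times <= -0.5)
        assert np.allclose(out.power[..., sel].mean(axis=(0, 3)), 0.0,
                           atol=1e-10)

    def test_nonpositive_baseline_raises(self):
        tf = flat_tf(0.0)
        with pytest.raises(NumericalError):
            spectral.baseline_correct(tf, (-1.0, -0.5))


class TestExtractBandPeak:
    def relative_tf(self, n_locs=3):
        tf = flat_tf(1.0, n_trials=2, n_locs=n_locs)
        return spectral.baseline_correct(tf, (-1.0, -0.5))

    def test_single_hot_bin_found(self):
        tf = self.relative_tf()
        fi = int(np.argmax(np.isclose(tf.freqs, 43.0)))
        ti = tf.times >= 0
        tf.power[:, 1, fi, ti] = 2.0
        peak = spectral.extract_band_peak(tf, marks_for(tf), "slow-gamma")
        assert peak.peak_frequency == 43.0
        assert peak.peak_location == 1
        assert peak.power > 1.0

    def test_mode_min_finds_suppressed_bin(self):
        tf = self.relative_tf()
        fi = int(np.argmax(np.isclose(tf.freqs, 35.0)))
        tf.power[:, 2, fi, tf.times >= 0] = -0.8
        peak = spectral.extract_band_peak(tf, marks_for(tf), "slow-gamma",
                                          mode="min")
        assert peak.peak_frequency == 35.0
        assert peak.peak_location == 2
        assert peak.power < 0.0

    def test_tie_broken_by_lowest_frequency_then_location(self):
        tf = self.relative_tf()
        for f in (40.0, 45.0):
            fi = int(np.argmax(np.isclose(tf.freqs, f)))
            tf.power[:, :, fi, tf.times >= 0] = 3.0
        peak = spectral.extract_band_peak(tf, marks_for(tf), "slow-gamma")
        assert peak.peak_frequency == 40.0
        assert peak.peak_location == 0

    def test_roi_mask_restricts_search(self):
        tf = self.relative_tf()
        fi = int(np.argmax(np.isclose(tf.freqs, 43.0)))
        tf.power[:, 0, fi, tf.times >= 0] = 9.0
        tf.power[:, 2, fi, tf.times >= 0] = 5.0
        roi = np.array([False, False, True])
        peak = spectral.extract_band_peak(tf, marks_for(tf), "slow-gamma",
                                          roi_mask=roi)
        assert peak.peak_location == 2

    def test_empty_roi_rejected(self):
        tf = self.relative_tf()
        with pytest.raises(InputError):
            spectral.extract_band_peak(tf, marks_for(tf), "slow-gamma",
                                       roi_mask=np.zeros(3, bool))

    def test_permutation_of_trials_leaves_peak_unchanged(self):
        g = np.random.default_rng(9)
        tf = self.relative_tf()
        tf.power += g.normal(0, 0.1, tf.power.shape)
        marks = marks_for(tf)
        p1 = spectral.extract_band_peak(tf, marks, "slow-gamma")
        perm = np.array([1, 0])
        tf2 = TfPower(power=tf.power[perm], freqs=tf.freqs, times=tf.times,
                      kind="relative")
        p2 = spectral.extract_band_peak(tf2, marks.iloc[perm].reset_index(),
                                        "slow-gamma")
        assert p1 == p2


class TestPowerMap:
    def test_consistent_with_band_peak(self):
        g = np.random.default_rng(4)
        tf = flat_tf(1.0, n_trials=3, n_locs=4)
        tf.power *= g.uniform(0.5, 2.0, tf.power.shape)
        rel = spectral.baseline_correct(tf, (-1.0, -0.5))
        marks = marks_for(rel)
        peak = spectral.extract_band_peak(rel, marks, "slow-gamma")
        pmap = spectral.power_map(rel, marks, peak.peak_frequency)
        assert int(np.argmax(pmap)) == peak.peak_location
        assert pmap[peak.peak_location] == pytest.approx(peak.power)

    def test_uniform_data_give_constant_map(self):
        rel = spectral.baseline_correct(flat_tf(1.0), (-1.0, -0.5))
        pmap = spectral.power_map(rel, marks_for(rel), 43.0)
        assert np.allclose(pmap, pmap[0])

    def test_off_grid_frequency_rejected(self):
        rel = spectral.baseline_correct(flat_tf(1.0), (-1.0, -0.5))
        with pytest.raises(InputError):
            spectral.power_map(rel, marks_for(rel), 43.5)
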