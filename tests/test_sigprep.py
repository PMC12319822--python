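"""Conditioning: resampling, filtering, GESD, bad segments."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from gammaflow import sigprep
from gammaflow.containers import BANDS, Recording
from gammaflow.errors import ConfigError, InputError
from oracles import gesd_oracle
from conftest import make_noise_recording


def sine_recording(freq, fs=1000.0, duration=10.0, events=None):
    t = np.arange(int(duration * fs)) / fs
    data = np.sin(2 * np.pi * freq * t)[None, :]
    if events is None:
        events = pd.DataFrame({"sample": [], "label": []})
    return Recording(data=data, channel_groups=np.array(["MEG"], dtype=object),
                     sampling_rate=fs, events=events)


def rms(x):
    return float(np.sqrt(np.mean(np.square(x))))


class TestResample:
    def test_exact_ratio_halves_samples_and_events(self):
        rec = sine_recording(40.0, fs=1000.0, duration=10.0,
                             events=pd.DataFrame({"sample": [1000],
                                                  "label": ["go"]}))
        out = sigprep.resample(rec, 500.0)
        assert out.n_samples == 5000
        assert out.sampling_rate == 500.0
        assert out.events["sample"].iloc[0] == 500

    def test_passband_tone_amplitude_preserved(self):
        rec = sine_recording(40.0, fs=1000.0)
        out = sigprep.resample(rec, 500.0)
        # interior region, away from polyphase edge effects
        mid = out.data[0, 500:-500]
        assert abs(rms(mid) - np.sqrt(0.5)) / np.sqrt(0.5) < 0.01

    def test_upsampling_rejected(self):
        rec = sine_recording(40.0, fs=500.0)
        with pytest.raises(ConfigError):
            sigprep.resample(rec, 1000.0)
        with pytest.raises(ConfigError):
            sigprep.resample(rec, -5.0)


class TestFilterBand:
    def test_notch_kills_line_tone(self):
        rec = sine_recording(50.0, fs=500.0)
        out = sigprep.filter_band(rec, 1.0, 245.0, notches=((49.0, 55.0),))
        assert rms(out.data[0, 500:-500]) < 0.03 * np.sqrt(0.5)

    def test_passband_tone_survives(self):
        rec = sine_recording(20.0, fs=500.0)
        out = sigprep.filter_band(rec, 1.0, 245.0, notches=((49.0, 55.0),))
        assert abs(rms(out.data[0, 500:-500]) - np.sqrt(0.5)) < 0.05 * np.sqrt(0.5)

    def test_zero_in_zero_out(self):
        rec = sine_recording(20.0, fs=500.0)
        rec.data[:] = 0.0
        out = sigprep.filter_band(rec, 1.0, 245.0, notches=((49.0, 51.0),))
        assert np.allclose(out.data, 0.0)

    def test_band_crossing_nyquist_rejected(self):
        rec = sine_recording(20.0, fs=500.0)
        with pytest.raises(ConfigError):
            sigprep.filter_band(rec, 1.0, 260.0)
        with pytest.raises(ConfigError):
            sigprep.filter_band(rec, 1.0, 95.0, notches=((240.0, 260.0),))

    def test_passband_idempotence(self):
        rec = sine_recording(20.0, fs=500.0)
        once = sigprep.filter_band(rec, 13.0, 30.0)
        twice = sigprep.filter_band(once, 13.0, 30.0)
        r1 = rms(once.data[0, 500:-500])
        r2 = rms(twice.data[0, 500:-500])
        assert abs(r2 - r1) / r1 < 0.01

    def test_emg_channel_passes_untouched(self):
        rec = make_noise_recording(n_channels=3, groups=["MEG", "MEG", "EMG"])
        before = rec.data[2].copy()
        out = sigprep.filter_band(rec, 13.0, 30.0)
        assert np.array_equal(out.data[2], before)
        assert not np.array_equal(out.data[0], rec.data[0])

    @pytest.mark.parametrize("band", sorted(BANDS))
    def test_band_split_confines_spectral_mass(self, band):
        rec = make_noise_recording(n_channels=1, duration_s=60.0, seed=7)
        lo, hi = BANDS[band]
        out = sigprep.filter_band(rec, lo, hi)
        x = out.data[0]
        spec = np.abs(np.fft.rfft(x)) ** 2
        freqs = np.fft.rfftfreq(x.size, 1 / rec.sampling_rate)
        inside = spec[(freqs >= lo) & (freqs <= hi)].sum()
        assert spec.sum() > 0
        assert 1 - inside / spec.sum() < 0.05


class TestGesd:
    def test_single_gross_outlier(self):
        x = np.array([1.0] * 9 + [100.0])
        assert list(sigprep.gesd(x)) == [9]

    def test_constant_vector_clean(self):
        assert sigprep.gesd(np.ones(10)).size == 0

    def test_three_injected_outliers_recovered_exactly(self):
        g = np.random.default_rng(5)
        x = g.standard_normal(100)
        idx = [10, 50, 90]
        x[idx] = [10.0, -11.0, 12.0]
        assert sorted(sigprep.gesd(x)) == idx

    def test_short_input_rejected(self):
        with pytest.raises(InputError):
            sigprep.gesd(np.array([1.0, 2.0]))

    @given(st.integers(min_value=0, max_value=400))
    def test_matches_exhaustive_oracle_small_n(self, seed):
        g = np.random.default_rng(seed)
        n = int(g.integers(3, 13))
        x = g.standard_normal(n)
        if g.random() < 0.5:  # sometimes plant an outlier
            x[int(g.integers(0, n))] += g.choice([-1, 1]) * g.uniform(4, 20)
        assert set(sigprep.gesd(x).tolist()) == gesd_oracle(x)

    @given(st.integers(min_value=0, max_value=100))
    def test_flags_at_most_k_max(self, seed):
        g = np.random.default_rng(seed)
        n = int(g.integers(5, 40))
        x = g.standard_normal(n) * g.uniform(0.1, 10)
        out = sigprep.gesd(x)
        assert out.size <= int(np.ceil(0.2 * n))
        assert np.all((out >= 0) & (out < n))


class TestBadSegments:
    def test_variance_burst_window_flagged(self):
        rec = make_noise_recording(n_channels=4, duration_s=40.0, seed=3)
        w = int(rec.sampling_rate)
        rec.data[:, 17 * w : 18 * w] *= 20.0
        mask = sigprep.detect_bad_segments(rec)
        assert mask.flagged == (17,)

    def test_identical_windows_unflagged(self):
        fs = 500.0
        tile = np.random.default_rng(0).standard_normal((2, int(fs)))
        data = np.tile(tile, (1, 12))
        rec = Recording(data=data, channel_groups=np.array(["MEG", "MEG"],
                                                           dtype=object),
                        sampling_rate=fs)
        assert sigprep.detect_bad_segments(rec).flagged == ()

    def test_coverage_capped_at_20_percent(self):
        rec = make_noise_recording(n_channels=2, duration_s=30.0, seed=9)
        w = int(rec.sampling_rate)
        for k in range(12):  # more contamination than the cap allows
            rec.data[:, k * w : (k + 1) * w] *= 30.0
        mask = sigprep.detect_bad_segments(rec)
        assert mask.coverage_fraction <= 0.2 + 1e-9

    def test_emg_channel_exempt(self):
        rec = make_noise_recording(n_channels=3, duration_s=30.0, seed=4,
                                   groups=["MEG", "MEG", "EMG"])
        w = int(rec.sampling_rate)
        rec.data[2, 10 * w : 11 * w] *= 50.0  # burst only on EMG
        assert sigprep.detect_bad_segments(rec).flagged == ()
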