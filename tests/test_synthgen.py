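"""Synthetic-data generator: schedules, recordings, MEPs, population."""

import numpy as np
import pytest
from scipy import signal as sg

from gammaflow.errors import ConfigError
from gammaflow.synthgen import (
    BandTruth,
    ML1_SEQUENCE,
    SimConfig,
    make_movement_truth,
    make_trial_schedule,
    simulate_mep_trials,
    simulate_ml1,
    simulate_population,
    simulate_recording,
)
from dataclasses import replace


class TestSchedule:
    def test_ma1_design_counts(self):
        sched = make_trial_schedule("MA1", seed=0)
        assert sched["trial"].nunique() == 70
        assert (sched["label"] == "nogo").sum() == 14  # 20% of 70
        assert (sched["label"] == "go").sum() == 56

    def test_ma1_timing(self):
        sched = make_trial_schedule("MA1", seed=1)
        cues = sched[sched["label"] == "cue"].set_index("trial")["time_s"]
        stims = sched[sched["label"].isin(("go", "nogo"))
                      ].set_index("trial")["time_s"]
        assert np.allclose(stims - cues, 1.0)  # cue-stimulus gap
        itis = cues.to_numpy()[1:] - stims.to_numpy()[:-1] - 0.2
        assert np.all((itis >= 2.0) & (itis <= 4.0))

    def test_exp3_variant(self):
        sched = make_trial_schedule("MA1-exp3", seed=2)
        assert (sched["label"] == "go").sum() == 140
        assert (sched["label"] == "nogo").sum() == 0
        cues = sched[sched["label"] == "cue"]["time_s"].to_numpy()
        stims = sched[sched["label"] == "go"]["time_s"].to_numpy()
        itis = np.round(cues[1:] - stims[:-1] - 0.2, 6)
        assert set(itis).issubset({2.7, 3.2, 3.7, 4.2, 4.7})

    def test_ma2_paced_presses(self):
        sched = make_trial_schedule("MA2", seed=3)
        flashes = sched[sched["label"] == "flash"]
        assert len(flashes) == 4 * 8 * 8  # digits x flashes x cycles
        assert np.allclose(np.diff(flashes["time_s"]), 1.0)

    def test_unknown_task_rejected(self):
        with pytest.raises(ConfigError):
            make_trial_schedule("MA9", seed=0)

    def test_deterministic_given_seed(self):
        a = make_trial_schedule("MA1", seed=5)
        b = make_trial_schedule("MA1", seed=5)
        assert a.equals(b)


@pytest.fixture(scope="module")
def small():
    cfg = SimConfig(seed=4, task_id="MA1", n_trials=6, snr=20.0,
                    line_noise_amp=0.0)
    sched = make_trial_schedule("MA1", seed=4)
    sched = sched[sched["trial"] < 6].reset_index(drop=True)
    truth = make_movement_truth(sched, cfg, seed=4)
    rec, lead = simulate_recording(cfg, sched, truth, seed=4)
    return cfg, sched, truth, rec, lead


class TestRecording:
    def test_bit_identical_for_identical_seed(self, small):
        cfg, sched, truth, rec, lead = small
        rec2, lead2 = simulate_recording(cfg, sched, truth, seed=4)
        assert np.array_equal(rec.data, rec2.data)
        assert np.array_equal(lead.gain, lead2.gain)
        assert rec.events.equals(rec2.events)

    def test_emg_burst_exceeds_5x_baseline_rms(self, small):
        cfg, sched, truth, rec, lead = small
        emg = rec.data[rec.channel_indices("EMG")[0]]
        fs = rec.sampling_rate
        burst, base = [], []
        for _, row in truth.iterrows():
            burst.append(emg[int((row.onset_s + 0.05) * fs):
                             int((row.offset_s - 0.05) * fs)])
            g = row.go_time_s
            base.append(emg[int((g - 0.6) * fs): int((g - 0.2) * fs)])
        rms = lambda v: np.sqrt(np.mean(np.concatenate(v) ** 2))
        assert rms(burst) > 5 * rms(base)

    def test_movement_spectrum_peaks_at_configured_frequency(self):
        cfg = SimConfig(seed=9, task_id="MA1", n_trials=10, snr=60.0,
                        line_noise_amp=0.0)
        bt = dict(cfg.band_truth)
        bt["slow-gamma"] = replace(bt["slow-gamma"], center_hz=43.0)
        cfg = cfg.with_updates(band_truth=bt)
        sched = make_trial_schedule("MA1", seed=9)
        sched = sched[sched["trial"] < 10].reset_index(drop=True)
        truth = make_movement_truth(sched, cfg, seed=9)
        rec, lead = simulate_recording(cfg, sched, truth, seed=9)
        fs = rec.sampling_rate
        segs = [rec.data[:24, int(a * fs): int(b * fs)]
                for a, b in zip(truth.onset_s, truth.offset_s + 0.4)]
        x = np.concatenate(segs, axis=1)
        freqs, psd = sg.welch(x, fs=fs, nperseg=256)
        band = (freqs >= 35) & (freqs <= 57)
        peak = freqs[band][np.argmax(psd.mean(axis=0)[band])]
        assert abs(peak - 43.0) <= 1.0

    def test_event_samples_match_schedule(self, small):
        cfg, sched, truth, rec, lead = small
        assert len(rec.events) == len(sched)
        assert (rec.events["sample"]
                == (sched["time_s"] * rec.sampling_rate).round().astype(int)
                ).all()

    def test_nonpositive_snr_rejected(self):
        with pytest.raises(ConfigError):
            SimConfig(snr=0.0)

    def test_low_sampling_rate_rejected(self):
        with pytest.raises(ConfigError):
            SimConfig(sampling_rate=150.0)

    def test_band_truth_outside_band_rejected(self):
        with pytest.raises(ConfigError):
            SimConfig(band_truth={
                "slow-gamma": BandTruth(center_hz=75.0,
                                        profile="offset-peak")})


class TestMepTrials:
    def test_design_counts(self):
        cfg = SimConfig(seed=0)
        assert len(simulate_mep_trials(cfg, "spMEP_early", 15, seed=1)) == 15
        assert len(simulate_mep_trials(cfg, "SICI1ms", 13, seed=1)) == 13

    def test_zero_contamination_never_trips_precontraction_rule(self):
        from gammaflow import tmsmep
        cfg = SimConfig(seed=0)
        cfg.mep_model.precontraction_prob = 0.0
        for seed in range(4):
            df = simulate_mep_trials(cfg, "spMEP", 15, seed=seed)
            out = tmsmep.reject_trials(df)
            assert not (out["reason"] == "prepulse>0.1mV").any()

    def test_unknown_protocol_and_bad_count_rejected(self):
        cfg = SimConfig(seed=0)
        with pytest.raises(ConfigError):
            simulate_mep_trials(cfg, "tripleSICI", 10, seed=0)
        with pytest.raises(ConfigError):
            simulate_mep_trials(cfg, "spMEP", 0, seed=0)

    def test_deterministic_given_seed(self):
        cfg = SimConfig(seed=0)
        a = simulate_mep_trials(cfg, "SICI2.5ms", 15, seed=7)
        b = simulate_mep_trials(cfg, "SICI2.5ms", 15, seed=7)
        assert a.equals(b)


class TestMl1Session:
    def test_sequence_key_counts_are_3322(self):
        counts = sorted(np.bincount(ML1_SEQUENCE).tolist(), reverse=True)
        assert counts == [3, 3, 2, 2]

    def test_block_structure(self):
        df = simulate_ml1(SimConfig(seed=0), seed=1)
        assert df["block"].nunique() == 15
        for b in (1, 15):
            blk = df[df["block"] == b]
            assert len(blk) == 30
            assert (blk["block_type"] == "random").all()
        blk2 = df[df["block"] == 2]
        assert len(blk2) == 30  # 3 repeats of the 10-item sequence
        assert blk2["cue"].tolist() == list(ML1_SEQUENCE) * 3


class TestPopulation:
    def test_null_correlation_small_at_n50(self):
        cfg = SimConfig(seed=1, n_subjects=50, trait_corr=0.0)
        truth, subs = simulate_population(cfg)
        assert abs(truth.latent_r) < 0.3
        assert len(subs) == 50

    def test_target_correlation_recovered_at_n200(self):
        cfg = SimConfig(seed=2, n_subjects=200, trait_corr=0.7)
        truth, _ = simulate_population(cfg)
        assert 0.6 <= truth.latent_r <= 0.8

    def test_mean_latent_r_unbiased_over_replicates(self):
        rs = []
        for seed in range(100):
            cfg = SimConfig(seed=seed, n_subjects=50, trait_corr=0.4)
            truth, _ = simulate_population(cfg)
            rs.append(truth.latent_r)
        assert abs(np.mean(rs) - 0.4) < 0.05

    def test_too_few_subjects_rejected(self):
        with pytest.raises(ConfigError):
            simulate_population(SimConfig(seed=0, n_subjects=2))

    def test_invalid_trait_corr_rejected(self):
        with pytest.raises(ConfigError):
            SimConfig(trait_corr=1.5)

    def test_traits_propagate_to_subject_configs(self):
        cfg = SimConfig(seed=3, n_subjects=10, trait_corr=0.9)
        truth, subs = simulate_population(cfg)
        for i, sub in enumerate(subs):
            assert sub.config.band_truth["slow-gamma"].center_hz == \
                pytest.approx(truth.table.loc[i, "slow_gamma_peak_hz"])
            assert sub.config.mep_model.sici_ratio["SICI2.5ms"] == \
                pytest.approx(truth.table.loc[i, "sici_ratio"])
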