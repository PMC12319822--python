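"""Sensor normalisation and LCMV beamforming."""

import numpy as np
import pytest

from gammaflow import beamform, sigprep
from gammaflow.beamform import Leadfield
from gammaflow.errors import InputError, NumericalError
from gammaflow.synthgen import BandTruth, SimConfig, SubjectSim


def random_spd(n, seed=0, cond=10.0):
    g = np.random.default_rng(seed)
    q, _ = np.linalg.qr(g.standard_normal((n, n)))
    lam = np.linspace(1.0, cond, n)
    return (q * lam) @ q.T


class TestEigenNormalize:
    def test_divides_by_smallest_covariance_eigenvalue(self):
        g = np.random.default_rng(1)
        data = g.standard_normal((4, 5000))
        groups = np.array(["MEG"] * 4, dtype=object)
        out, scales = beamform.eigen_normalize(data, groups)
        lam_min = np.linalg.eigvalsh(np.cov(data))[0]
        assert scales["MEG"] == pytest.approx(lam_min)
        assert np.allclose(out, data / lam_min)

    def test_global_scaling_by_3_divides_output_by_3(self):
        g = np.random.default_rng(2)
        data = g.standard_normal((4, 5000))
        groups = np.array(["MEG"] * 4, dtype=object)
        out1, _ = beamform.eigen_normalize(data, groups)
        out3, scales3 = beamform.eigen_normalize(3.0 * data, groups)
        # eigenvalues scale by 9, so the x3 data come out 3x smaller
        assert np.allclose(out3, out1 / 3.0)

    def test_groups_normalised_independently(self):
        g = np.random.default_rng(3)
        data = g.standard_normal((5, 4000))
        data[3:] *= 100.0
        groups = np.array(["GRAD"] * 3 + ["MAG"] * 2, dtype=object)
        out, scales = beamform.eigen_normalize(data, groups)
        assert set(scales) == {"GRAD", "MAG"}
        assert scales["MAG"] > scales["GRAD"]

    def test_emg_left_untouched(self):
        g = np.random.default_rng(4)
        data = g.standard_normal((3, 2000))
        groups = np.array(["MEG", "MEG", "EMG"], dtype=object)
        out, scales = beamform.eigen_normalize(data, groups)
        assert np.array_equal(out[2], data[2])
        assert "EMG" not in scales

    def test_rank_deficient_group_raises(self):
        g = np.random.default_rng(5)
        row = g.standard_normal(1000)
        data = np.vstack([row, row])  # perfectly collinear
        with pytest.raises(NumericalError):
            beamform.eigen_normalize(data, np.array(["MEG", "MEG"],
                                                    dtype=object))


class TestLcmvWeights:
    def test_unit_gain_identity_holds(self):
        cov = random_spd(8, seed=0)
        gain = np.random.default_rng(1).standard_normal((12, 8))
        w = beamform.lcmv_weights(cov, gain, rank=8)
        assert np.allclose(np.einsum("sc,sc->s", w, gain), 1.0, atol=1e-8)

    def test_rank_above_channels_clipped_with_warning(self):
        cov = random_spd(6, seed=2)
        gain = np.random.default_rng(3).standard_normal((4, 6))
        with pytest.warns(UserWarning, match="clipping"):
            w = beamform.lcmv_weights(cov, gain, rank=50)
        assert np.allclose(np.einsum("sc,sc->s", w, gain), 1.0, atol=1e-8)

    def test_asymmetric_covariance_rejected(self):
        cov = np.arange(16, dtype=float).reshape(4, 4)
        with pytest.raises(InputError):
            beamform.lcmv_weights(cov, np.eye(4), rank=4)

    def test_invariant_to_global_sensor_scaling(self):
        g = np.random.default_rng(7)
        data = g.standard_normal((6, 4000))
        groups = np.array(["MEG"] * 6, dtype=object)
        gain = g.standard_normal((10, 6))
        out1, s1 = beamform.eigen_normalize(data, groups)
        out2, s2 = beamform.eigen_normalize(5.0 * data, groups)
        lf = Leadfield(gain=gain, grid_coords=np.zeros((10, 3)),
                       grid_shape=(10, 1, 1), spacing=1.0)
        w1 = beamform.lcmv_weights(np.cov(out1),
                                   beamform.scale_leadfield(lf, groups, s1))
        w2 = beamform.lcmv_weights(np.cov(out2),
                                   beamform.scale_leadfield(lf, groups, s2))
        # unit gain makes reconstruction equivariant: 5x sensor data
        # yield exactly 5x the physical source estimate
        src1 = beamform.project(out1, w1)
        src2 = beamform.project(out2, w2)
        assert np.allclose(src2, 5.0 * src1, rtol=1e-6, atol=1e-9)


class TestProject:
    def test_identity_weights_return_channels(self):
        epochs = np.random.default_rng(0).standard_normal((3, 2, 100))
        out = beamform.project(epochs, np.eye(2))
        assert np.allclose(out, epochs)

    def test_zero_epochs_give_zero_sources(self):
        out = beamform.project(np.zeros((2, 4, 50)),
                               np.random.default_rng(1).standard_normal((6, 4)))
        assert np.allclose(out, 0.0)

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(InputError):
            beamform.project(np.zeros((2, 4, 50)), np.zeros((6, 5)))


class TestLocalisation:
    def test_point_source_found_at_true_grid_index(self):
        cfg = SimConfig(seed=42, grid_shape=(3, 3, 3), snr=10.0,
                        task_id="MA1", n_trials=15)
        true_idx = 7
        cfg = cfg.with_updates(band_truth={
            "slow-gamma": BandTruth(center_hz=43.0, profile="movement",
                                    source_index=true_idx,
                                    baseline_level=0.1)})
        sub = SubjectSim(subject=0, seed=42, config=cfg, traits={})
        rec, lead, _ = sub.recording()
        band = sigprep.filter_band(rec, 30.0, 60.0, notches=((49.0, 51.0),))
        rows = np.flatnonzero(band.channel_groups != "EMG")
        data, scales = beamform.eigen_normalize(band.data[rows],
                                                band.channel_groups[rows])
        lf = beamform.scale_leadfield(lead, band.channel_groups[rows], scales)
        w = beamform.lcmv_weights(beamform.covariance(data), lf,
                                  rank=len(rows))
        est = int(np.argmax(beamform.variance_map(data, w)))
        step = np.abs(lead.grid_coords[est] - lead.grid_coords[true_idx]).max()
        assert step <= lead.spacing + 1e-9

    def test_noiseless_projection_concentrates_variance(self):
        # single source driven through the leadfield with no noise: the
        # on-source projected variance dwarfs the off-source variance
        g = np.random.default_rng(11)
        cfg = SimConfig(seed=3, grid_shape=(5, 5, 5))
        from gammaflow.synthgen import make_leadfield
        lead = make_leadfield(cfg)
        src = 62
        wave = g.standard_normal(4000)
        data = np.outer(lead.gain[src], wave)
        cov = np.cov(data) + 1e-9 * np.eye(lead.n_channels)
        w = beamform.lcmv_weights(cov, lead, rank=lead.n_channels)
        var = beamform.variance_map(data, w)
        off = np.delete(var, src)
        assert np.nanmax(off) / var[src] < 0.1
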