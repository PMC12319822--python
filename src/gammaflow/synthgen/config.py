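"""Simulation configuration and ground-truth parameter models.

Defaults encode the study conditions the pipeline is designed around:
a Go/NoGo motor activation task of 70 trials (20% NoGo, 1 s
cue–stimulus gap, 2–4 s ITI), 15 TMS trials per protocol (13 in the
rest-TMS variant), movement-related band activity with subject-typical
peak frequencies (β ≈ 19 Hz, slow-γ ≈ 43 Hz, mid-γ ≈ 71 Hz), and
15-block sequence-learning sessions.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

from gammaflow.containers import BANDS
from gammaflow.errors import ConfigError

__all__ = ["BandTruth", "MepModel", "LearningModel", "SimConfig",
           "MEP_PROTOCOLS", "TASK_IDS"]

TASK_IDS = ("MA1", "MA1-exp3", "MA2")

MEP_PROTOCOLS = (
    "spMEP", "SICI1ms", "SICI2.5ms",
    "spMEP_early", "spMEP_late", "SICI_early", "SICI_late",
)

#: conditioned protocol -> its unconditioned (test-pulse-only) partner
SICI_PAIRS = {
    "SICI1ms": "spMEP",
    "SICI2.5ms": "spMEP",
    "SICI_early": "spMEP_early",
    "SICI_late": "spMEP_late",
}


@dataclass
class BandTruth:
    """Ground-truth oscillatory activity for one band.

    ``center_hz`` is the subject's true peak frequency; ``amplitude``
    scales the movement-locked envelope relative to the band's
    baseline level; ``profile`` selects the temporal shape
    (``"erd-ers"`` for β: suppression during movement then a ~1 s
    rebound after offset; ``"offset-peak"`` for slow-γ: a burst peaking
    at movement offset; ``"movement"`` for mid-γ: a burst spanning
    onset→offset).  ``source_index`` places the activity on the source
    grid (None → a default location near the grid centre).
    """

    center_hz: float
    amplitude: float = 1.0
    profile: str = "movement"
    source_index: int | None = None
    bandwidth_hz: float = 4.0
    baseline_level: float = 0.25


@dataclass
class MepModel:
    """Log-normal MEP amplitude model (mV).

    The unconditioned (test-pulse-only) amplitude has log-mean
    ``sp_log_mean_mv`` (0 → geometric mean 1 mV, the 1 mV-MT
    convention); conditioned protocols scale it by their SICI ratio.
    ``precontraction_prob`` and ``subthreshold_prob`` inject trials
    that the rejection rules must catch.
    """

    sp_log_mean_mv: float = 0.0
    log_sd: float = 0.2
    sici_ratio: dict[str, float] = field(default_factory=lambda: {
        "SICI1ms": 0.50, "SICI2.5ms": 0.55,
        "SICI_early": 0.65, "SICI_late": 0.50,
    })
    precontraction_prob: float = 0.03
    subthreshold_prob: float = 0.02
    prepulse_baseline_mv: float = 0.02


@dataclass
class LearningModel:
    """Behavioural learning-curve parameters for both tasks.

    ML task 1 (sequence RT): block-mean RT decays exponentially from
    ``ml1_initial_ms`` to ``ml1_asymptote_ms`` across sequence blocks
    at rate ``ml1_rate`` per block; random blocks stay at the initial
    level (the sequence advantage is absent).  ML task 2 (visuomotor):
    trial movement time decays from ``ml2_initial_mt_s`` to
    ``ml2_asymptote_mt_s`` with time-on-task constant ``ml2_tau_s``,
    angular error likewise; the session runs until ``ml2_total_s``
    seconds of cumulative movement time.
    """

    ml1_initial_ms: float = 420.0
    ml1_asymptote_ms: float = 330.0
    ml1_rate: float = 0.4
    ml1_noise_ms: float = 30.0
    ml1_anticipatory_prob: float = 0.01
    ml1_error_prob: float = 0.03
    ml2_initial_mt_s: float = 12.0
    ml2_asymptote_mt_s: float = 8.0
    ml2_tau_s: float = 400.0
    ml2_mt_noise: float = 0.06
    ml2_initial_error_deg: float = 12.0
    ml2_asymptote_error_deg: float = 5.0
    ml2_error_noise: float = 0.2
    ml2_total_s: float = 1182.0  # ~19.7 min time-on-task


def default_band_truth() -> dict[str, BandTruth]:
    return {
        "beta": BandTruth(center_hz=19.0, amplitude=0.8, profile="erd-ers",
                          baseline_level=1.0),
        "slow-gamma": BandTruth(center_hz=43.0, amplitude=1.0,
                                profile="offset-peak"),
        "mid-gamma": BandTruth(center_hz=71.0, amplitude=1.0, profile="movement"),
    }


@dataclass
class SimConfig:
    """Top-level simulation configuration.

    ``snr`` is the array-level in-band signal-to-noise ratio: per band,
    the movement-window signal RMS summed over the sensor array divided
    by one channel's noise RMS within that band's frequency range (the
    convention under which beamformer output SNR tracks the parameter).
    ``emg_snr`` is the ratio of within-burst to baseline EMG RMS.
    ``trait_corr`` is the target Pearson correlation between the two
    latent traits named in ``traits`` at the population level.
    """

    seed: int = 0
    n_subjects: int = 10
    sampling_rate: float = 500.0
    n_channels: dict[str, int] = field(
        default_factory=lambda: {"GRAD": 16, "MAG": 8}
    )
    grid_shape: tuple[int, int, int] = (3, 3, 3)
    grid_spacing: float = 8.0
    band_truth: dict[str, BandTruth] = field(default_factory=default_band_truth)
    snr: float = 5.0
    task_id: str = "MA1"
    n_trials: int | None = None  # None -> the task's own design count
    mep_model: MepModel = field(default_factory=MepModel)
    learning_model: LearningModel = field(default_factory=LearningModel)
    trait_corr: float = 0.0
    traits: tuple[str, str] = ("slow_gamma_peak_hz", "sici_ratio")
    emg_snr: float = 8.0
    noise_pink_fraction: float = 0.5
    noise_lowfreq_amp: float = 2.0  # RMS of the < 8 Hz background, x broadband
    noise_drift: float = 0.1  # slow RMS nonstationarity (fractional)
    line_noise_hz: float = 50.0
    line_noise_amp: float = 2.0  # x noise RMS
    rt_mean_s: float = 0.25
    rt_sd_s: float = 0.05
    mt_mean_s: float = 0.45
    mt_sd_s: float = 0.08

    def __post_init__(self) -> None:
        if self.sampling_rate <= 2 * 90.0:
            raise ConfigError("sampling_rate must exceed twice the highest "
                              "band edge (90 Hz)")
        if not self.snr > 0:
            raise ConfigError("snr must be positive")
        if abs(self.trait_corr) > 1:
            raise ConfigError("|trait_corr| must not exceed 1")
        if self.task_id not in TASK_IDS:
            raise ConfigError(f"unknown task_id {self.task_id!r}; "
                              f"expected one of {TASK_IDS}")
        for band, truth in self.band_truth.items():
            lo, hi = BANDS[band]
            if not (lo <= truth.center_hz <= hi):
                raise ConfigError(
                    f"{band} truth {truth.center_hz} Hz outside [{lo}, {hi}]"
                )

    def with_updates(self, **kwargs) -> "SimConfig":
        return replace(self, **kwargs)
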