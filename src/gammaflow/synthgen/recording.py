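"""Continuous-recording simulation: leadfield, sources, sensors, EMG.

The sensor model is ``data = gain x source activity + noise``: each
band's activity is a narrowband noise carrier at the subject's true
peak frequency, amplitude-modulated by a movement-locked envelope
(Hann-tapered boxcars / Hann bumps over the windows the temporal
profiles describe), placed at a single source of a small volumetric
grid and projected through a synthetic distance-decay leadfield.
Background noise is a configurable white + 1/f pink mixture scaled to
the requested SNR, plus a common 50 Hz line sinusoid.  The EMG channel
carries broadband bursts from true movement onset to offset at
``emg_snr`` times the baseline RMS.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import signal

from gammaflow.beamform import Leadfield
from gammaflow.containers import Recording
from gammaflow.errors import ConfigError, InputError
from gammaflow.synthgen.config import SimConfig

__all__ = ["make_leadfield", "make_movement_truth", "simulate_recording"]

#: relative physical scale per coil type (exercises eigen-normalisation)
GROUP_SCALE = {"GRAD": 1.0, "MAG": 0.05, "EEG": 1.0}

BETA_ERD_DEPTH = 0.6  # fractional amplitude drop during movement


def make_leadfield(config: SimConfig) -> Leadfield:
    """Distance-decay gain matrix on a regular 3-D grid.

    Sources sit on a ``grid_shape`` lattice with ``grid_spacing``
    units; sensors on a jittered plane two spacings above the grid.
    The gain falls off as 1 / (d² + (spacing/2)²), giving smooth,
    full-rank columns with a realistic depth gradient.  Geometry is
    deterministic given ``config.seed``.
    """
    nx, ny, nz = config.grid_shape
    h = config.grid_spacing
    gx, gy, gz = np.meshgrid(
        (np.arange(nx) - (nx - 1) / 2) * h,
        (np.arange(ny) - (ny - 1) / 2) * h,
        (np.arange(nz) - (nz - 1) / 2) * h,
        indexing="ij",
    )
    coords = np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])
    n_meg = sum(config.n_channels.values())
    rng = np.random.default_rng(np.random.SeedSequence((config.seed, 0xC0)))
    side = int(np.ceil(np.sqrt(n_meg)))
    span = max((nx - 1), (ny - 1)) * h + 2 * h
    cx, cy = np.meshgrid(np.linspace(-span / 2, span / 2, side),
                         np.linspace(-span / 2, span / 2, side))
    ch = np.column_stack([cx.ravel(), cy.ravel(),
                          np.full(side * side, gz.max() + 2 * h)])[:n_meg]
    ch[:, :2] += rng.uniform(-0.2 * h, 0.2 * h, size=(n_meg, 2))
    d2 = ((coords[:, None, :] - ch[None, :, :]) ** 2).sum(axis=2)
    gain = 1.0 / (d2 + (h / 2) ** 2)
    return Leadfield(gain=gain, grid_coords=coords,
                     grid_shape=config.grid_shape, spacing=h)


def default_source_indices(config: SimConfig) -> dict[str, int]:
    """Distinct default source locations per band, near the grid centre."""
    nx, ny, nz = config.grid_shape
    center = np.ravel_multi_index((nx // 2, ny // 2, nz // 2), config.grid_shape)
    n_src = nx * ny * nz
    offsets = {"beta": -1, "slow-gamma": 0, "mid-gamma": 1}
    out = {}
    for band, truth in config.band_truth.items():
        if truth.source_index is not None:
            out[band] = truth.source_index
        else:
            out[band] = int(np.clip(center + offsets.get(band, 0), 0, n_src - 1))
    return out


def make_movement_truth(schedule: pd.DataFrame, config: SimConfig,
                        seed: int) -> pd.DataFrame:
    """True movement onset/offset times for every Go-type event.

    Reaction and movement times are truncated-normal draws around the
    configured means.  Returns columns ``trial, go_time_s, onset_s,
    offset_s`` (absolute session times).
    """
    rng = np.random.default_rng(np.random.SeedSequence((seed, 0x30)))
    go = schedule[schedule["label"].isin(("go", "flash"))]
    rt = np.maximum(rng.normal(config.rt_mean_s, config.rt_sd_s, len(go)), 0.08)
    mt = np.maximum(rng.normal(config.mt_mean_s, config.mt_sd_s, len(go)), 0.15)
    onset = go["time_s"].to_numpy() + rt
    return pd.DataFrame({
        "trial": go["trial"].to_numpy(),
        "go_time_s": go["time_s"].to_numpy(),
        "onset_s": onset,
        "offset_s": onset + mt,
    })


def _smooth_box(t: np.ndarray, a: float, b: float, taper_s: float = 0.1) -> np.ndarray:
    """Boxcar over [a, b] with half-Hann ramps of ``taper_s`` inside."""
    taper = min(taper_s, max((b - a) / 2, 1e-3))
    out = np.zeros_like(t)
    rise = (t >= a) & (t < a + taper)
    out[rise] = 0.5 * (1 - np.cos(np.pi * (t[rise] - a) / taper))
    out[(t >= a + taper) & (t <= b - taper)] = 1.0
    fall = (t > b - taper) & (t <= b)
    out[fall] = 0.5 * (1 - np.cos(np.pi * (b - t[fall]) / taper))
    return out


def _hann_bump(t: np.ndarray, center: float, width_s: float) -> np.ndarray:
    """Hann window of total width ``width_s`` centred at ``center``."""
    x = (t - center) / width_s
    out = np.zeros_like(t)
    sel = np.abs(x) <= 0.5
    out[sel] = 0.5 * (1 + np.cos(2 * np.pi * x[sel]))
    return out


def band_envelope(t: np.ndarray, truth, onsets: np.ndarray,
                  offsets: np.ndarray) -> np.ndarray:
    """Movement-locked amplitude envelope for one band's carrier.

    For the γ profiles the carrier exists only during the movement
    response (the baseline holds broadband background instead); for
    the β profile the carrier is the ongoing rhythm itself — present
    at unit amplitude in the baseline, suppressed during movement and
    rebounding for ~1 s after the offset.
    """
    if truth.profile == "erd-ers":
        env = np.ones_like(t)
        for a, b in zip(onsets, offsets):
            env -= BETA_ERD_DEPTH * _smooth_box(t, a - 0.2, b)
            env += truth.amplitude * _smooth_box(t, b + 0.1, b + 1.0)
        return np.maximum(env, 0.0)
    env = np.zeros_like(t)
    for a, b in zip(onsets, offsets):
        if truth.profile == "movement":
            env += truth.amplitude * _smooth_box(t, a, b)
        elif truth.profile == "offset-peak":
            env += truth.amplitude * _hann_bump(t, b, 0.8)
        else:
            raise ConfigError(f"unknown temporal profile {truth.profile!r}")
    return env


def _narrowband_carrier(rng: np.random.Generator, n: int, fs: float,
                        center_hz: float, bandwidth_hz: float) -> np.ndarray:
    lo = max(center_hz - bandwidth_hz / 2, 0.5)
    hi = min(center_hz + bandwidth_hz / 2, fs / 2 - 0.5)
    sos = signal.butter(2, [lo, hi], btype="bandpass", fs=fs, output="sos")
    x = signal.sosfiltfilt(sos, rng.standard_normal(n))
    return x / np.sqrt(np.mean(x**2))


def _pink_noise(rng: np.random.Generator, shape: tuple[int, int]) -> np.ndarray:
    white = rng.standard_normal(shape)
    spec = np.fft.rfft(white, axis=1)
    f = np.fft.rfftfreq(shape[1])
    f[0] = f[1]
    spec /= np.sqrt(f)
    pink = np.fft.irfft(spec, n=shape[1], axis=1)
    return pink / np.sqrt(np.mean(pink**2, axis=1, keepdims=True))


def simulate_recording(
    config: SimConfig,
    schedule: pd.DataFrame,
    movement_truth: pd.DataFrame,
    seed: int,
) -> tuple[Recording, Leadfield]:
    """Simulate the continuous sensor recording for one session.

    Returns the recording (MEG-like channel groups plus one EMG
    channel) and the leadfield that generated it.
    """
    if len(schedule) == 0:
        raise InputError("schedule must contain at least one event")
    fs = config.sampling_rate
    rng = np.random.default_rng(np.random.SeedSequence((seed, 0x51)))
    duration = float(schedule["time_s"].max()) + 5.0
    n = int(round(duration * fs))
    t = np.arange(n) / fs
    lead = make_leadfield(config)
    n_meg = lead.n_channels

    onsets = movement_truth["onset_s"].to_numpy()
    offsets = movement_truth["offset_s"].to_numpy()

    # unit-RMS background noise with slow amplitude nonstationarity
    # (real recordings drift; a perfectly stationary background makes
    # any event-related power change an extreme outlier to GESD)
    p = config.noise_pink_fraction
    noise = (np.sqrt(1 - p) * rng.standard_normal((n_meg, n))
             + np.sqrt(p) * _pink_noise(rng, (n_meg, n)))
    sos_slow = signal.butter(2, 0.1, btype="lowpass", fs=fs, output="sos")
    drift = signal.sosfiltfilt(sos_slow, rng.standard_normal(n))
    drift = 1.0 + config.noise_drift * drift / max(drift.std(), 1e-12)
    noise *= drift
    # dominant low-frequency background (delta/theta/alpha range), as in
    # real M/EEG where broadband variance is carried by slow rhythms
    if config.noise_lowfreq_amp > 0:
        sos_lf = signal.butter(2, 8.0, btype="lowpass", fs=fs, output="sos")
        lf = signal.sosfiltfilt(sos_lf, rng.standard_normal((n_meg, n)), axis=1)
        lf /= np.sqrt(np.mean(lf**2, axis=1, keepdims=True))
        noise = noise + config.noise_lowfreq_amp * lf * drift

    active = np.zeros(n, dtype=bool)
    for a, b in zip(onsets, offsets):
        active[int(max(a - 0.2, 0) * fs) : int(min(b + 1.0, duration) * fs)] = True
    if not active.any():
        active[:] = True

    from gammaflow.containers import BANDS

    sensor_sig = np.zeros((n_meg, n))
    src_idx = default_source_indices(config)
    for band, truth in config.band_truth.items():
        lo, hi = BANDS.get(band, (truth.center_hz - 15, truth.center_hz + 15))
        carrier = _narrowband_carrier(rng, n, fs, truth.center_hz,
                                      truth.bandwidth_hz)
        env = band_envelope(t, truth, onsets, offsets)
        # broadband in-band background at the source: keeps the
        # baseline spectrum non-degenerate, like ongoing cortical 1/f
        sos_band = signal.butter(2, [max(lo, 0.5), min(hi, fs / 2 - 1)],
                                 btype="bandpass", fs=fs, output="sos")
        background = signal.sosfiltfilt(sos_band, rng.standard_normal(n))
        background /= np.sqrt(np.mean(background**2))
        src_wave = carrier * env + truth.baseline_level * background
        sig_b = np.outer(lead.gain[src_idx[band]], src_wave)
        sos = signal.butter(4, [max(lo, 0.5), min(hi, fs / 2 - 1)],
                            btype="bandpass", fs=fs, output="sos")
        inband_noise_rms = np.sqrt(np.mean(signal.sosfiltfilt(sos, noise[0]) ** 2))
        # array-level SNR: signal power summed over the array against the
        # in-band noise power of one channel, the convention under which
        # beamformer output SNR tracks the parameter directly
        rms_b = np.sqrt(np.sum(np.mean(sig_b[:, active] ** 2, axis=1)))
        if rms_b > 0:
            sensor_sig += sig_b * (config.snr * inband_noise_rms / rms_b)

    line_gain = rng.uniform(0.5, 1.0, n_meg)
    line = np.outer(line_gain,
                    np.sin(2 * np.pi * config.line_noise_hz * t
                           + rng.uniform(0, 2 * np.pi)))
    data = sensor_sig + noise + config.line_noise_amp * line

    # per-coil-type physical scale (applied to data *and* leadfield, as
    # a real forward model would absorb sensor gains)
    groups: list[str] = []
    for gname, count in config.n_channels.items():
        groups.extend([gname] * count)
    gain = lead.gain.copy()
    for gname in config.n_channels:
        rows = [i for i, g in enumerate(groups) if g == gname]
        data[rows] *= GROUP_SCALE.get(gname, 1.0)
        gain[:, rows] *= GROUP_SCALE.get(gname, 1.0)
    lead = Leadfield(gain=gain, grid_coords=lead.grid_coords,
                     grid_shape=lead.grid_shape, spacing=lead.spacing)

    # EMG channel: baseline noise, multiplicative burst onset -> offset
    emg_noise = rng.standard_normal(n)
    burst = np.zeros(n)
    for a, b in zip(onsets, offsets):
        burst = np.maximum(burst, _smooth_box(t, a, b, taper_s=0.02))
    emg = emg_noise * (1.0 + (config.emg_snr - 1.0) * burst)
    data = np.vstack([data, emg])
    groups.append("EMG")

    events = pd.DataFrame({
        "sample": np.minimum((schedule["time_s"].to_numpy() * fs).round(), n - 1
                             ).astype(int),
        "label": schedule["label"].to_numpy(),
    })
    rec = Recording(data=data, channel_groups=np.array(groups, dtype=object),
                    sampling_rate=fs, events=events)
    return rec, lead
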