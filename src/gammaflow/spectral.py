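"""Multitaper time-frequency decomposition and band-peak extraction.

Power is estimated per sliding window by averaging DPSS-tapered
periodograms (window 1.6 s, step 200 ms, half-bandwidth 2.5 Hz → 7
tapers by default), on a frequency grid with 1 Hz spacing.  Baseline
correction divides out the trial-mean baseline power per frequency and
location, yielding relative change (P − B) / B.

Feature extraction follows the movement-locked averaging scheme: per
trial, corrected power is averaged over that trial's own movement
window (onset→offset, or offset→offset+1 s for the post-movement β
rebound, with epochs re-locked to the offset); the trial average is
then reduced over frequency × ROI locations by max (ERS) or min (ERD),
defining the subject's power, peak frequency and peak location.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.signal import windows

from gammaflow.containers import BANDS, BandPeak
from gammaflow.errors import ConfigError, InputError, NumericalError

__all__ = ["TfPower", "multitaper_tf", "baseline_correct", "extract_band_peak",
           "power_map"]


@dataclass
class TfPower:
    """Time-frequency power for epoched data.

    ``power`` has shape ``(n_trials, n_locations, n_freqs, n_times)``;
    ``freqs`` (Hz) and ``times`` (s, window centres relative to the lock
    event) label the trailing axes.  ``kind`` is ``"absolute"`` after
    :func:`multitaper_tf` and ``"relative"`` after
    :func:`baseline_correct`.
    """

    power: np.ndarray
    freqs: np.ndarray
    times: np.ndarray
    kind: str = "absolute"

    @property
    def n_trials(self) -> int:
        return self.power.shape[0]

    @property
    def n_locations(self) -> int:
        return self.power.shape[1]


def multitaper_tf(
    epochs: np.ndarray,
    sampling_rate: float,
    t_start: float,
    fmin: float,
    fmax: float,
    window_s: float = 1.6,
    step_s: float = 0.2,
    freq_step: float = 1.0,
    half_bandwidth: float = 2.5,
) -> TfPower:
    """DPSS multitaper spectrogram of epoched data.

    ``epochs`` is ``(trials, locations, samples)`` with the time axis
    starting at ``t_start`` seconds relative to the lock event.  Windows
    are placed fully inside the epoch on a ``step_s`` grid; each window
    is timestamped at its centre.  The output frequency grid has
    ``freq_step`` spacing and covers ``[fmin, fmax]`` inclusive.
    """
    epochs = np.asarray(epochs, dtype=float)
    if epochs.ndim == 2:
        epochs = epochs[:, None, :]
    if epochs.ndim != 3:
        raise InputError("epochs must be (trials, locations, samples)")
    fs = sampling_rate
    win_n = int(round(window_s * fs))
    if epochs.shape[-1] < win_n:
        raise InputError("epoch shorter than the analysis window")
    nw = window_s * half_bandwidth
    n_tapers = int(2 * nw - 1)
    if n_tapers < 1:
        raise ConfigError("half_bandwidth too small for the window length")
    tapers = windows.dpss(win_n, nw, Kmax=n_tapers)  # (K, win_n)

    # Zero-pad so the FFT grid lands exactly on multiples of freq_step.
    base = fs / freq_step
    m = int(np.ceil(win_n / base))
    nfft = int(round(m * base))
    stride = m
    all_freqs = np.fft.rfftfreq(nfft, 1 / fs)
    fsel = np.arange(0, all_freqs.size, stride)
    freqs = all_freqs[fsel]
    keep = (freqs >= fmin - 1e-9) & (freqs <= fmax + 1e-9)
    fsel, freqs = fsel[keep], freqs[keep]
    if freqs.size == 0:
        raise ConfigError("no frequency bins inside the requested band")

    n_samp = epochs.shape[-1]
    dur = n_samp / fs
    # window centres on the step grid, windows fully inside the epoch
    first = np.ceil((t_start + window_s / 2) / step_s - 1e-9) * step_s
    centers = []
    c = first
    while c + window_s / 2 <= t_start + dur + 1e-9:
        centers.append(round(c / step_s) * step_s)
        c += step_s
    times = np.array(centers)
    if times.size == 0:
        raise InputError("epoch too short for a single window")

    power = np.empty(epochs.shape[:2] + (freqs.size, times.size))
    scale = 2.0 / (fs * np.sum(tapers[0] ** 2))
    for k, tc in enumerate(times):
        a = int(round((tc - window_s / 2 - t_start) * fs))
        seg = epochs[..., a : a + win_n]
        seg = seg - seg.mean(axis=-1, keepdims=True)
        tapered = seg[:, :, None, :] * tapers  # (T, L, K, win_n)
        spec = np.fft.rfft(tapered, n=nfft, axis=-1)[..., fsel]
        power[..., k] = scale * np.mean(np.abs(spec) ** 2, axis=2)
    return TfPower(power=power, freqs=freqs, times=times, kind="absolute")


def baseline_correct(tf: TfPower, baseline_window: tuple[float, float]) -> TfPower:
    """Relative-change baseline correction using the across-trial mean.

    The baseline ``B`` is the mean absolute power over the baseline time
    bins *and* over all trials, per frequency × location; the output is
    ``(P − B) / B``.  By construction the trial-average of corrected
    power over the baseline window is zero.
    """
    if tf.kind != "absolute":
        raise InputError("baseline_correct expects absolute power")
    lo, hi = baseline_window
    sel = (tf.times >= lo - 1e-9) & (tf.times <= hi + 1e-9)
    if not sel.any():
        raise InputError("baseline window contains no time bins")
    b = tf.power[..., sel].mean(axis=(0, 3), keepdims=True)
    if (b <= 0).any():
        raise NumericalError("non-positive baseline power")
    return replace(tf, power=(tf.power - b) / b, kind="relative")


def _trial_time_average(tf: TfPower, marks: pd.DataFrame, window: str) -> np.ndarray:
    """Average power over each trial's own movement window → (T, L, F)."""
    if len(marks) != tf.n_trials:
        raise InputError("marks must contain one row per trial in the epochs")
    out = np.empty(tf.power.shape[:3])
    mts = marks["mt_s"].to_numpy(dtype=float)
    for t in range(tf.n_trials):
        if window == "onset-offset":
            lo, hi = 0.0, mts[t]  # epochs locked to onset
        elif window == "offset-plus-1s":
            lo, hi = 0.0, 1.0  # epochs locked to offset
        else:
            raise ConfigError(f"unknown averaging window {window!r}")
        sel = (tf.times >= lo - 1e-9) & (tf.times <= hi + 1e-9)
        if not sel.any():  # movement shorter than one time step
            sel = np.isclose(tf.times, round(lo / 0.2) * 0.2)
        if not sel.any():
            raise InputError(f"no time bins inside the window of trial {t}")
        out[t] = tf.power[t][:, :, sel].mean(axis=-1)
    return out


def extract_band_peak(
    tf: TfPower,
    marks: pd.DataFrame,
    band: str | tuple[float, float],
    mode: str = "max",
    roi_mask: np.ndarray | None = None,
    window: str = "onset-offset",
) -> BandPeak:
    """Subject-level peak power / frequency / location for one band.

    ``tf`` must be baseline-corrected power for the retained trials;
    ``marks`` the matching movement marks.  ``mode`` is ``"max"`` for an
    ERS or ``"min"`` for an ERD.  Ties are broken by the lowest
    frequency, then the lowest location index.
    """
    if tf.kind != "relative":
        raise InputError("extract_band_peak expects baseline-corrected power")
    if mode not in ("max", "min"):
        raise ConfigError("mode must be 'max' or 'min'")
    lo, hi = BANDS[band] if isinstance(band, str) else band
    locs = np.arange(tf.n_locations) if roi_mask is None else np.flatnonzero(roi_mask)
    if locs.size == 0:
        raise InputError("empty ROI")
    fsel = np.flatnonzero((tf.freqs >= lo - 1e-9) & (tf.freqs <= hi + 1e-9))
    if fsel.size == 0:
        raise InputError("band contains no frequency bins")
    avg = _trial_time_average(tf, marks, window).mean(axis=0)  # (L, F)
    sub = avg[np.ix_(locs, fsel)].T  # (F, L): freq-major for tie-breaking
    flat = np.argmax(sub) if mode == "max" else np.argmin(sub)
    fi, li = np.unravel_index(flat, sub.shape)
    return BandPeak(
        band=band if isinstance(band, str) else f"{lo}-{hi}",
        power=float(sub[fi, li]),
        peak_frequency=float(tf.freqs[fsel[fi]]),
        peak_location=int(locs[li]),
        window=window,
        mode=mode,
    )


def power_map(
    tf: TfPower,
    marks: pd.DataFrame,
    peak_frequency: float,
    window: str = "onset-offset",
) -> np.ndarray:
    """Movement-window power at a fixed frequency, one value per location."""
    fi = np.flatnonzero(np.isclose(tf.freqs, peak_frequency))
    if fi.size == 0:
        raise InputError(f"{peak_frequency} Hz is not on the frequency grid")
    avg = _trial_time_average(tf, marks, window).mean(axis=0)  # (L, F)
    return avg[:, fi[0]]
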