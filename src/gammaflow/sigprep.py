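"""Continuous-data conditioning.

Resampling, zero-phase band-pass/notch filtering, band splitting, and
GESD-based bad-segment detection.  All filters run forward-backward
(:func:`scipy.signal.sosfiltfilt`) so event latencies are preserved.

The outlier detector is Rosner's generalised extreme studentised
deviate (GESD) test: up to ``k_max`` candidates are removed one at a
time (always the sample with the largest studentised deviation), each
removal i yielding a statistic ``R_i`` and a critical value
``lambda_i`` from the t distribution; the declared outliers are the
first ``i*`` removals where ``i*`` is the *largest* i with
``R_i > lambda_i``.
"""

from __future__ import annotations

from fractions import Fraction

import numpy as np
from scipy import signal, stats

from gammaflow.containers import BANDS, Recording, SegmentMask
from gammaflow.errors import ConfigError, InputError

__all__ = [
    "BANDS",
    "resample",
    "filter_band",
    "band_split",
    "gesd",
    "gesd_critical_values",
    "detect_bad_segments",
    "epoch_data",
]


def _round_half_away(x: np.ndarray) -> np.ndarray:
    """Round to nearest integer, halves away from zero."""
    return np.sign(x) * np.floor(np.abs(x) + 0.5)


def resample(recording: Recording, target_rate: float) -> Recording:
    """Polyphase anti-aliased resampling to ``target_rate`` Hz.

    Event sample indices are rescaled by the rate ratio with
    round-half-away-from-zero and clipped into the new time axis.
    """
    if target_rate <= 0:
        raise ConfigError("target_rate must be positive")
    if target_rate > recording.sampling_rate:
        raise ConfigError("target_rate must not exceed the sampling rate")
    ratio = Fraction(target_rate / recording.sampling_rate).limit_denominator(1000)
    up, down = ratio.numerator, ratio.denominator
    data = signal.resample_poly(recording.data, up, down, axis=1)
    events = recording.events.copy()
    if len(events):
        new_idx = _round_half_away(events["sample"].to_numpy() * (up / down))
        events["sample"] = np.clip(new_idx, 0, data.shape[1] - 1).astype(int)
    return Recording(
        data=data,
        channel_groups=recording.channel_groups.copy(),
        sampling_rate=recording.sampling_rate * up / down,
        events=events,
    )


def _notch_sos(low: float, high: float, fs: float) -> np.ndarray:
    # Chebyshev-II band-stop: guarantees >= 30 dB attenuation across the
    # whole stop interval (doubled by filtfilt), unlike a low-order
    # Butterworth stop whose attenuation collapses off-centre.
    return signal.cheby2(3, 30.0, [low, high], btype="bandstop", fs=fs, output="sos")


def filter_band(
    recording: Recording,
    low_hz: float,
    high_hz: float,
    notches: tuple[tuple[float, float], ...] = (),
    skip_groups: tuple[str, ...] = ("EMG",),
) -> Recording:
    """Zero-phase band-pass plus optional notch filtering.

    Channels in ``skip_groups`` (EMG by default) pass through untouched;
    their content is signal for the movement detector, not artifact.
    """
    fs = recording.sampling_rate
    nyq = fs / 2
    if not (0 < low_hz < high_hz < nyq):
        raise ConfigError(f"band ({low_hz}, {high_hz}) must lie inside (0, {nyq})")
    for lo, hi in notches:
        if not (0 < lo < hi < nyq):
            raise ConfigError(f"notch ({lo}, {hi}) must lie inside (0, {nyq})")
    out = recording.copy()
    rows = np.flatnonzero(~np.isin(recording.channel_groups, skip_groups))
    if rows.size == 0:
        return out
    x = out.data[rows]
    sos = signal.butter(4, [low_hz, high_hz], btype="bandpass", fs=fs, output="sos")
    x = signal.sosfiltfilt(sos, x, axis=1)
    for lo, hi in notches:
        x = signal.sosfiltfilt(_notch_sos(lo, hi, fs), x, axis=1)
    out.data[rows] = x
    return out


def band_split(recording: Recording, bands: dict[str, tuple[float, float]] | None = None
               ) -> dict[str, Recording]:
    """Filter a recording into each analysis band separately."""
    bands = BANDS if bands is None else bands
    return {name: filter_band(recording, lo, hi) for name, (lo, hi) in bands.items()}


def gesd_critical_values(n: int, k_max: int, alpha: float) -> np.ndarray:
    """Rosner's critical values ``lambda_i`` for i = 1..k_max."""
    lam = np.empty(k_max)
    for i in range(1, k_max + 1):
        m = n - i + 1  # sample size at step i
        p = 1.0 - alpha / (2.0 * m)
        t = stats.t.ppf(p, m - 2)
        lam[i - 1] = (m - 1) * t / np.sqrt((m - 2 + t**2) * m)
    return lam


def gesd(
    values: np.ndarray,
    alpha: float = 0.05,
    max_outlier_fraction: float = 0.2,
) -> np.ndarray:
    """Indices of outliers under Rosner's sequential ESD test.

    ``k_max = ceil(max_outlier_fraction * n)`` candidates are tested;
    ties in the studentised deviation are broken by the lowest index.
    A zero-variance input yields no outliers.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1 or x.size < 3:
        raise InputError("gesd requires a 1-D array of length >= 3")
    if not (0 < alpha < 1):
        raise ConfigError("alpha must lie in (0, 1)")
    n = x.size
    k_max = int(np.ceil(max_outlier_fraction * n))
    k_max = min(k_max, n - 2)  # need >= 2 points left for a t quantile
    if k_max < 1:
        return np.array([], dtype=int)
    lam = gesd_critical_values(n, k_max, alpha)
    remaining = np.arange(n)
    removed = []
    r_stats = []
    for i in range(k_max):
        xi = x[remaining]
        s = np.std(xi, ddof=1)
        if s == 0 or not np.isfinite(s):
            break
        dev = np.abs(xi - np.mean(xi))
        j = int(np.argmax(dev))  # argmax returns the lowest index on ties
        r_stats.append(dev[j] / s)
        removed.append(remaining[j])
        remaining = np.delete(remaining, j)
    n_out = 0
    for i, r in enumerate(r_stats):
        if r > lam[i]:
            n_out = i + 1
    return np.sort(np.array(removed[:n_out], dtype=int))


def detect_bad_segments(
    recording: Recording,
    window_s: float = 1.0,
    alpha: float = 0.05,
    max_fraction: float = 0.2,
    exclude_groups: tuple[str, ...] = ("EMG",),
) -> SegmentMask:
    """Flag artifactual windows of a continuous recording.

    The signal standard deviation is pooled across all non-EMG channels
    in non-overlapping windows of ``window_s`` seconds; the resulting
    per-window series is screened with :func:`gesd` (significance
    ``alpha``, at most ``max_fraction`` of windows).
    """
    w = int(round(window_s * recording.sampling_rate))
    n_win = recording.n_samples // w
    if n_win < 3:
        raise InputError("recording must span at least 3 windows")
    rows = np.flatnonzero(~np.isin(recording.channel_groups, exclude_groups))
    seg = recording.data[rows, : n_win * w].reshape(len(rows), n_win, w)
    metric = seg.transpose(1, 0, 2).reshape(n_win, -1).std(axis=1, ddof=1)
    flagged = gesd(metric, alpha=alpha, max_outlier_fraction=max_fraction)
    return SegmentMask(window_s=window_s, flagged=tuple(int(i) for i in flagged),
                       n_windows=n_win)


def epoch_data(
    data: np.ndarray,
    sampling_rate: float,
    center_samples: np.ndarray,
    pre_s: float,
    post_s: float,
    bad_mask: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Cut ``[center - pre_s, center + post_s)`` epochs from continuous data.

    Returns ``(epochs, kept)`` where ``epochs`` has shape
    ``(n_kept, n_channels, n_samples)`` and ``kept`` holds the indices of
    the centers whose epoch lies fully inside the recording and does not
    overlap a flagged sample of ``bad_mask``.
    """
    n_pre = int(round(pre_s * sampling_rate))
    n_post = int(round(post_s * sampling_rate))
    epochs, kept = [], []
    for i, c in enumerate(np.asarray(center_samples, dtype=int)):
        a, b = c - n_pre, c + n_post
        if a < 0 or b > data.shape[1]:
            continue
        if bad_mask is not None and bad_mask[a:b].any():
            continue
        epochs.append(data[:, a:b])
        kept.append(i)
    if not epochs:
        return np.empty((0, data.shape[0], n_pre + n_post)), np.array([], dtype=int)
    return np.stack(epochs), np.array(kept, dtype=int)
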