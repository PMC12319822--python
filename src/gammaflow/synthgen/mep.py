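"""Synthetic TMS motor-evoked-potential trials."""

from __future__ import annotations

import zlib

import numpy as np
import pandas as pd

from gammaflow.errors import ConfigError
from gammaflow.synthgen.config import MEP_PROTOCOLS, SICI_PAIRS, SimConfig

__all__ = ["simulate_mep_trials", "make_mep_trace"]

EXP1_TRIALS_PER_PROTOCOL = 15
EXP3_TRIALS_PER_CONDITION = 13


def _protocol_log_mean(config: SimConfig, protocol: str) -> float:
    m = config.mep_model
    if protocol in SICI_PAIRS:  # conditioned protocols
        return m.sp_log_mean_mv + np.log(m.sici_ratio[protocol])
    return m.sp_log_mean_mv


def simulate_mep_trials(
    config: SimConfig,
    protocol: str,
    n_trials: int,
    seed: int,
    block: int = 1,
) -> pd.DataFrame:
    """Log-normal peak-to-peak MEP amplitudes for one protocol.

    A configurable fraction of trials carries pre-pulse EMG above the
    0.1 mV precontraction threshold, and another fraction a
    sub-threshold (< 0.1 mV) response, so the downstream rejection
    rules are exercised.  Columns: ``protocol, block, trial, p2p_mv,
    prepulse_mv``.
    """
    if protocol not in MEP_PROTOCOLS:
        raise ConfigError(f"unknown protocol {protocol!r}; "
                          f"expected one of {MEP_PROTOCOLS}")
    if n_trials < 1:
        raise ConfigError("n_trials must be >= 1")
    m = config.mep_model
    tag = zlib.crc32(protocol.encode())  # stable across interpreter runs
    rng = np.random.default_rng(np.random.SeedSequence((seed, tag)))
    p2p = rng.lognormal(_protocol_log_mean(config, protocol), m.log_sd, n_trials)
    sub = rng.random(n_trials) < m.subthreshold_prob
    p2p[sub] = rng.uniform(0.0, 0.08, int(sub.sum()))
    prepulse = np.abs(rng.normal(0.0, m.prepulse_baseline_mv, n_trials))
    contaminated = rng.random(n_trials) < m.precontraction_prob
    prepulse[contaminated] = 0.1 + rng.exponential(0.1, int(contaminated.sum()))
    return pd.DataFrame({
        "protocol": protocol,
        "block": block,
        "trial": np.arange(n_trials),
        "p2p_mv": p2p,
        "prepulse_mv": prepulse,
    })


def make_mep_trace(
    p2p_mv: float,
    sampling_rate: float = 5000.0,
    duration_s: float = 0.1,
    latency_s: float = 0.022,
    noise_sd_mv: float = 0.0,
    seed: int = 0,
) -> np.ndarray:
    """A biphasic MEP waveform with programmed peak-to-peak amplitude.

    One cycle of a windowed sine starting at the response latency; the
    positive and negative lobes span exactly ``p2p_mv``.
    """
    n = int(round(duration_s * sampling_rate))
    t = np.arange(n) / sampling_rate
    wave = np.zeros(n)
    width = 0.012  # s, typical MEP duration
    sel = (t >= latency_s) & (t < latency_s + width)
    phase = (t[sel] - latency_s) / width
    wave[sel] = (p2p_mv / 2) * np.sin(2 * np.pi * phase)
    if noise_sd_mv > 0:
        wave += np.random.default_rng(seed).normal(0, noise_sd_mv, n)
    return wave
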