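"""Synthetic behavioural sessions for the two motor-learning tasks."""

from __future__ import annotations

import numpy as np
import pandas as pd

from gammaflow.synthgen.config import SimConfig

__all__ = ["ML1_SEQUENCE", "simulate_ml1", "simulate_ml2",
           "ml1_expected_score", "ml2_expected_score"]

#: fixed 10-item cue sequence; per-key counts are {3, 3, 2, 2}
ML1_SEQUENCE = (0, 1, 2, 0, 3, 1, 0, 2, 1, 3)
ML1_N_BLOCKS = 15
ML1_RANDOM_BLOCKS = (1, 15)
ML1_SEQUENCE_REPEATS = 3
ML1_RANDOM_CUES = 30


def _ml1_block_mean(model, block: int) -> float:
    """Expected RT (ms) for one block under the generator's curve."""
    if block in ML1_RANDOM_BLOCKS:
        return model.ml1_initial_ms  # no sequence advantage in random blocks
    decay = np.exp(-model.ml1_rate * (block - 2))
    return model.ml1_asymptote_ms + (model.ml1_initial_ms
                                     - model.ml1_asymptote_ms) * decay


def ml1_expected_score(model) -> float:
    """Closed-form expectation of the sequence-learning score (%)."""
    first = _ml1_block_mean(model, 2)
    plateau = np.mean([_ml1_block_mean(model, b) for b in range(10, 15)])
    return 100.0 * (plateau - first) / first


def simulate_ml1(config: SimConfig, seed: int) -> pd.DataFrame:
    """One sequence-learning session (15 blocks).

    Blocks 1 and 15 are random (30 cues each); blocks 2-14 contain 3
    repeats of the fixed 10-item sequence.  RTs follow the exponential
    learning curve plus Gaussian noise; occasional anticipatory
    (negative RT) and incorrect presses are injected.  Columns:
    ``block, trial, cue, rt_ms, correct, block_type``.
    """
    model = config.learning_model
    rng = np.random.default_rng(np.random.SeedSequence((seed, 0xB1)))
    rows = []
    for block in range(1, ML1_N_BLOCKS + 1):
        random_block = block in ML1_RANDOM_BLOCKS
        if random_block:
            cues = rng.integers(0, 4, ML1_RANDOM_CUES)
        else:
            cues = np.tile(ML1_SEQUENCE, ML1_SEQUENCE_REPEATS)
        mean_rt = _ml1_block_mean(model, block)
        for i, cue in enumerate(cues):
            rt = rng.normal(mean_rt, model.ml1_noise_ms)
            if rng.random() < model.ml1_anticipatory_prob:
                rt = -rng.uniform(0, 100)
            correct = rng.random() >= model.ml1_error_prob
            rows.append((block, i, int(cue), rt, correct,
                         "random" if random_block else "sequence"))
    return pd.DataFrame(rows, columns=["block", "trial", "cue", "rt_ms",
                                       "correct", "block_type"])


def _ml2_mt_curve(model, t_cum: float) -> float:
    decay = np.exp(-t_cum / model.ml2_tau_s)
    return model.ml2_asymptote_mt_s + (model.ml2_initial_mt_s
                                       - model.ml2_asymptote_mt_s) * decay


def _ml2_error_curve(model, t_cum: float) -> float:
    decay = np.exp(-t_cum / model.ml2_tau_s)
    return model.ml2_asymptote_error_deg + (model.ml2_initial_error_deg
                                            - model.ml2_asymptote_error_deg) * decay


def simulate_ml2(config: SimConfig, seed: int) -> pd.DataFrame:
    """One visuomotor session: trial-wise movement time and error.

    Trials are generated until the cumulative movement time reaches the
    configured time-on-task; expected values decay monotonically with
    time on task.  Columns: ``trial, mt_s, error_deg``.
    """
    model = config.learning_model
    rng = np.random.default_rng(np.random.SeedSequence((seed, 0xB2)))
    rows = []
    t_cum = 0.0
    trial = 0
    while t_cum < model.ml2_total_s:
        mt = _ml2_mt_curve(model, t_cum) * np.exp(
            rng.normal(0, model.ml2_mt_noise))
        err = _ml2_error_curve(model, t_cum) * np.exp(
            rng.normal(0, model.ml2_error_noise))
        rows.append((trial, mt, err))
        t_cum += mt
        trial += 1
    return pd.DataFrame(rows, columns=["trial", "mt_s", "error_deg"])


def ml2_expected_score(model, n_bins: int = 6) -> tuple[float, float]:
    """Deterministic bin-mean differences of the generator's decay curves.

    Evaluates the noise-free session (trial MTs exactly on the curve)
    and returns (delta movement time s, delta error deg) between the
    last and first bin of equal cumulative movement time.
    """
    mts, errs = [], []
    t_cum = 0.0
    while t_cum < model.ml2_total_s:
        mt = _ml2_mt_curve(model, t_cum)
        mts.append(mt)
        errs.append(_ml2_error_curve(model, t_cum))
        t_cum += mt
    mts = np.array(mts)
    errs = np.array(errs)
    cum = np.cumsum(mts)
    mid = cum - mts / 2
    width = cum[-1] / n_bins
    bins = np.minimum((mid / width).astype(int), n_bins - 1)
    d_mt = mts[bins == n_bins - 1].mean() - mts[bins == 0].mean()
    d_err = errs[bins == n_bins - 1].mean() - errs[bins == 0].mean()
    return float(d_mt), float(d_err)
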