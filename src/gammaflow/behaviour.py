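"""Motor-learning scores for the two behavioural tasks.

Sequence task (ML task 1): 15 blocks of key presses; blocks 1 and 15
are random, blocks 2–14 repeat a fixed 10-item sequence.  The learning
score is the percentage RT change from the first sequence block
(block 2) to the plateau blocks (10–14) after dropping incorrect
presses, anticipatory responses (RT ≤ 0 relative to the cue) and
per-block ±2 SD outliers — more negative means more learning.

Visuomotor tracking task (ML task 2): trial-wise movement times and
angular errors are divided into six bins of equal cumulative movement
time within the individual; the score is the bin-mean difference
last − first for each metric, again negative = learning.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from gammaflow.errors import InputError

__all__ = ["LearningScore", "ml1_score", "ml2_bin", "ml2_score"]

PLATEAU_BLOCKS = (10, 11, 12, 13, 14)
FIRST_SEQUENCE_BLOCK = 2


@dataclass(frozen=True)
class LearningScore:
    """Motor-learning summary; negative values mean more learning."""

    task: str
    value: float  # ML1: percent RT change; ML2: delta seconds
    delta_error: float | None = None  # ML2 only: delta degrees


def _clean_block_rts(rts: np.ndarray, sd_limit: float = 2.0) -> np.ndarray:
    """Single-pass ±2 SD cleaning within one block."""
    if rts.size < 2:
        return rts
    m, s = rts.mean(), rts.std(ddof=1)
    if s == 0:
        return rts
    return rts[np.abs(rts - m) <= sd_limit * s]


def ml1_score(session: pd.DataFrame) -> LearningScore:
    """Percent RT change from block 2 to the plateau (blocks 10-14).

    ``session`` needs columns ``block, rt_ms, correct``.  Incorrect and
    anticipatory (RT ≤ 0) trials are discarded, then per-block ±2 SD
    outliers, in a single pass.
    """
    required = {"block", "rt_ms", "correct"}
    if not required.issubset(session.columns):
        raise InputError(f"session must have columns {sorted(required)}")
    df = session[(session["correct"].astype(bool)) & (session["rt_ms"] > 0)]

    def block_mean(blocks: tuple[int, ...]) -> float:
        vals = []
        for b in blocks:
            rts = df.loc[df["block"] == b, "rt_ms"].to_numpy(dtype=float)
            rts = _clean_block_rts(rts)
            if rts.size == 0:
                raise InputError(f"block {b} has no retained reaction times")
            vals.append(rts.mean())
        return float(np.mean(vals))

    first = block_mean((FIRST_SEQUENCE_BLOCK,))
    plateau = block_mean(PLATEAU_BLOCKS)
    return LearningScore(task="ml1", value=100.0 * (plateau - first) / first)


def ml2_bin(session: pd.DataFrame, n_bins: int = 6) -> np.ndarray:
    """Assign trials to bins of equal cumulative movement time.

    Each trial goes to the bin containing the midpoint of its own
    movement-time interval on the cumulative clock.  Raises if any bin
    ends up empty.
    """
    if "mt_s" not in session.columns:
        raise InputError("session must have an mt_s column")
    mt = session["mt_s"].to_numpy(dtype=float)
    if mt.size < n_bins:
        raise InputError(f"need at least {n_bins} trials")
    if (mt <= 0).any():
        raise InputError("movement times must be positive")
    cum = np.cumsum(mt)
    mid = cum - mt / 2
    width = cum[-1] / n_bins
    bins = np.minimum((mid / width).astype(int), n_bins - 1)
    counts = np.bincount(bins, minlength=n_bins)
    if (counts == 0).any():
        empty = np.flatnonzero(counts == 0).tolist()
        raise InputError(f"bins {empty} contain no trials; fewer bins needed")
    return bins


def ml2_score(session: pd.DataFrame, n_bins: int = 6) -> LearningScore:
    """Practice-related change: bin-mean difference last − first."""
    bins = ml2_bin(session, n_bins=n_bins)
    mt = session["mt_s"].to_numpy(dtype=float)
    d_mt = mt[bins == n_bins - 1].mean() - mt[bins == 0].mean()
    d_err = None
    if "error_deg" in session.columns:
        err = session["error_deg"].to_numpy(dtype=float)
        d_err = float(err[bins == n_bins - 1].mean() - err[bins == 0].mean())
    return LearningScore(task="ml2", value=float(d_mt), delta_error=d_err)
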