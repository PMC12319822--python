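"""Trial schedules for the three motor activation task designs."""

from __future__ import annotations

import numpy as np
import pandas as pd

from gammaflow.errors import ConfigError

__all__ = ["make_trial_schedule"]

MA1_N_TRIALS = 70
MA1_NOGO_FRACTION = 0.2
MA1_CUE_STIM_GAP_S = 1.0
MA1_STIM_DUR_S = 0.2
MA1_ITI_RANGE_S = (2.0, 4.0)
MA1_EXP3_N_GO = 140
MA1_EXP3_ITIS_S = (2.7, 3.2, 3.7, 4.2, 4.7)
MA2_DIGITS = ("D2", "D3", "D4", "D5")
MA2_FLASHES_PER_DIGIT = 8
MA2_RATE_HZ = 1.0
MA2_N_CYCLES = 8
LEAD_IN_S = 4.0


def make_trial_schedule(task_id: str, seed: int = 0) -> pd.DataFrame:
    """Event table for one session of the given task design.

    Returns a DataFrame with columns ``trial, label, time_s``.  Labels
    are ``cue`` / ``go`` / ``nogo`` for the Go/NoGo designs and
    ``flash`` (with a ``digit`` column) for the paced-press design.

    * ``MA1`` — 70 trials, exactly 20% NoGo, 1 s cue–stimulus gap,
      inter-trial interval uniform in 2–4 s.
    * ``MA1-exp3`` — 140 Go trials, ITI drawn from
      {2.7, 3.2, 3.7, 4.2, 4.7} s.
    * ``MA2`` — cycles of 4 digits x 8 flashes at 1 Hz (32-flash
      cycles), repeated 8 times.
    """
    rng = np.random.default_rng(seed)
    rows: list[tuple] = []
    if task_id == "MA1":
        n = MA1_N_TRIALS
        n_nogo = int(round(MA1_NOGO_FRACTION * n))
        is_nogo = np.zeros(n, dtype=bool)
        is_nogo[rng.permutation(n)[:n_nogo]] = True
        t = LEAD_IN_S
        for trial in range(n):
            rows.append((trial, "cue", t))
            stim = t + MA1_CUE_STIM_GAP_S
            rows.append((trial, "nogo" if is_nogo[trial] else "go", stim))
            t = stim + MA1_STIM_DUR_S + rng.uniform(*MA1_ITI_RANGE_S)
    elif task_id == "MA1-exp3":
        t = LEAD_IN_S
        for trial in range(MA1_EXP3_N_GO):
            rows.append((trial, "cue", t))
            stim = t + MA1_CUE_STIM_GAP_S
            rows.append((trial, "go", stim))
            t = stim + MA1_STIM_DUR_S + rng.choice(MA1_EXP3_ITIS_S)
    elif task_id == "MA2":
        t = LEAD_IN_S
        trial = 0
        digits = []
        for _ in range(MA2_N_CYCLES):
            for digit in MA2_DIGITS:
                for _ in range(MA2_FLASHES_PER_DIGIT):
                    rows.append((trial, "flash", t))
                    digits.append(digit)
                    t += 1.0 / MA2_RATE_HZ
                    trial += 1
        df = pd.DataFrame(rows, columns=["trial", "label", "time_s"])
        df["digit"] = digits
        return df
    else:
        raise ConfigError(f"unknown task_id {task_id!r}")
    return pd.DataFrame(rows, columns=["trial", "label", "time_s"])
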