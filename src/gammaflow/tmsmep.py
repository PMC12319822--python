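"""MEP quantification, rule-based trial rejection, and SICI.

Rejection rules are applied in a fixed, documented order:

1. test-pulse amplitude < 0.1 mV (no reliable MEP);
2. pre-pulse EMG > 0.1 mV in the 80 ms before the pulse
   (precontraction);
3. per condition × block, amplitudes outside mean ± 2 SD (sample SD of
   the rule-1/2 survivors, candidate included);
4. per condition, a single two-sided Grubbs iteration at α = 0.05 on
   the remaining trials — at most one rejection per condition.

SICI is the ratio of the mean conditioned (paired-pulse) MEP amplitude
to the mean unconditioned (single-pulse) MEP amplitude over retained
trials; smaller ratios indicate stronger GABAergic inhibition.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from gammaflow.containers import SiciMeasure
from gammaflow.errors import InputError, NumericalError

__all__ = ["peak_to_peak", "grubbs_outlier", "reject_trials", "sici"]

MIN_MEP_MV = 0.1
MAX_PREPULSE_MV = 0.1


def peak_to_peak(emg_trace: np.ndarray, response_window: tuple[int, int]) -> float:
    """Max − min of the trace within ``response_window`` (sample indices)."""
    a, b = response_window
    seg = np.asarray(emg_trace, dtype=float)[a:b]
    if seg.size == 0:
        raise InputError("empty response window")
    return float(seg.max() - seg.min())


def grubbs_critical_value(n: int, alpha: float = 0.05) -> float:
    """Two-sided Grubbs critical value from the t distribution."""
    t = stats.t.ppf(1 - alpha / (2 * n), n - 2)
    return (n - 1) / np.sqrt(n) * np.sqrt(t**2 / (n - 2 + t**2))


def grubbs_outlier(values: np.ndarray, alpha: float = 0.05) -> int | None:
    """Index of the single Grubbs outlier, or None.

    One iteration of the two-sided test: the sample with the largest
    studentised deviation is rejected if its statistic exceeds the
    critical value.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 3:
        return None
    s = x.std(ddof=1)
    if s == 0:
        return None
    dev = np.abs(x - x.mean())
    j = int(np.argmax(dev))
    if dev[j] / s > grubbs_critical_value(x.size, alpha):
        return j
    return None


def reject_trials(
    trials: pd.DataFrame,
    min_mep_mv: float = MIN_MEP_MV,
    max_prepulse_mv: float = MAX_PREPULSE_MV,
    sd_limit: float = 2.0,
    grubbs_alpha: float = 0.05,
) -> pd.DataFrame:
    """Apply the ordered MEP rejection rules.

    ``trials`` needs columns ``protocol, block, p2p_mv, prepulse_mv``.
    Returns a copy with boolean ``rejected`` and string ``reason``
    columns; a trial is tagged with the first rule that rejects it.
    """
    required = {"protocol", "block", "p2p_mv", "prepulse_mv"}
    if not required.issubset(trials.columns):
        raise InputError(f"trials must have columns {sorted(required)}")
    out = trials.copy()
    out["rejected"] = False
    out["reason"] = ""

    def _reject(mask: pd.Series, reason: str) -> None:
        fresh = mask & ~out["rejected"]
        out.loc[fresh, "rejected"] = True
        out.loc[fresh, "reason"] = reason

    _reject(out["p2p_mv"] < min_mep_mv, "mep<0.1mV")
    _reject(out["prepulse_mv"] > max_prepulse_mv, "prepulse>0.1mV")

    # rule 3: condition x block +-2 SD, SD recomputed on rule-1/2 survivors
    for (_, _), grp in out[~out["rejected"]].groupby(["protocol", "block"]):
        if len(grp) < 3:
            continue
        amp = grp["p2p_mv"].to_numpy()
        m, s = amp.mean(), amp.std(ddof=1)
        bad = grp.index[np.abs(amp - m) > sd_limit * s]
        _reject(out.index.isin(bad), f"outside±{sd_limit:g}SD")

    # rule 4: one Grubbs iteration per condition on the survivors
    for _, grp in out[~out["rejected"]].groupby("protocol"):
        j = grubbs_outlier(grp["p2p_mv"].to_numpy(), alpha=grubbs_alpha)
        if j is not None:
            _reject(out.index == grp.index[j], "grubbs")
    return out


def sici(
    trials: pd.DataFrame,
    conditioned_label: str,
    unconditioned_label: str,
) -> SiciMeasure:
    """SICI ratio from a rejected-trial table.

    Uses retained trials only (the ``rejected`` column if present).
    """
    df = trials[~trials["rejected"]] if "rejected" in trials.columns else trials
    cond = df.loc[df["protocol"] == conditioned_label, "p2p_mv"].to_numpy()
    uncond = df.loc[df["protocol"] == unconditioned_label, "p2p_mv"].to_numpy()
    if cond.size < 1 or uncond.size < 1:
        raise InputError("need at least one retained trial per condition")
    um = float(uncond.mean())
    if um <= 0:
        raise NumericalError("unconditioned mean MEP amplitude is not positive")
    cm = float(cond.mean())
    return SiciMeasure(
        conditioned_mean=cm,
        unconditioned_mean=um,
        ratio=cm / um,
        n_conditioned=int(cond.size),
        n_unconditioned=int(uncond.size),
    )
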