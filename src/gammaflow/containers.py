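"""In-memory containers shared across pipeline stages.

Continuous data travel as :class:`Recording`; derived per-subject
quantities travel as small frozen dataclasses.  Trial-level tables
(movement marks, MEP trials, behavioural sessions) are plain pandas
DataFrames with documented columns — see the module that produces each.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from gammaflow.errors import InputError

#: Canonical frequency bands (Hz): β, slow-γ and mid-γ.
BANDS: dict[str, tuple[float, float]] = {
    "beta": (13.0, 30.0),
    "slow-gamma": (30.0, 60.0),
    "mid-gamma": (60.0, 90.0),
}


@dataclass
class Recording:
    """Continuous multichannel time series with events.

    Parameters
    ----------
    data
        Array of shape ``(n_channels, n_samples)``, arbitrary field units.
    channel_groups
        One label per channel, e.g. ``"GRAD"``, ``"MAG"``, ``"EEG"``,
        ``"EMG"``.  Group membership drives per-coil-type normalisation
        and exempts EMG from artifact statistics.
    sampling_rate
        Sampling rate in Hz.
    events
        DataFrame with integer column ``sample`` and string column
        ``label``; sample indices refer to this recording's time axis.
    """

    data: np.ndarray
    channel_groups: np.ndarray
    sampling_rate: float
    events: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame({"sample": [], "label": []})
    )

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.channel_groups = np.asarray(self.channel_groups, dtype=object)
        if self.data.ndim != 2 or self.data.shape[0] < 1:
            raise InputError("data must be a (channels x samples) array")
        if len(self.channel_groups) != self.data.shape[0]:
            raise InputError("one channel_groups label required per channel")
        if self.sampling_rate <= 0:
            raise InputError("sampling_rate must be positive")
        if len(self.events) and (
            (self.events["sample"] < 0).any()
            or (self.events["sample"] >= self.n_samples).any()
        ):
            raise InputError("event sample indices must lie within the recording")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        """Recording length in seconds."""
        return self.n_samples / self.sampling_rate

    def channel_indices(self, group: str) -> np.ndarray:
        """Indices of the channels belonging to ``group``."""
        return np.flatnonzero(self.channel_groups == group)

    def groups(self, exclude: tuple[str, ...] = ()) -> list[str]:
        """Distinct group labels in channel order, minus ``exclude``."""
        seen: list[str] = []
        for g in self.channel_groups:
            if g not in seen and g not in exclude:
                seen.append(g)
        return seen

    def copy(self) -> "Recording":
        return replace(
            self,
            data=self.data.copy(),
            channel_groups=self.channel_groups.copy(),
            events=self.events.copy(),
        )


@dataclass(frozen=True)
class SegmentMask:
    """Bad-segment mask over non-overlapping windows of a recording."""

    window_s: float
    flagged: tuple[int, ...]
    n_windows: int

    @property
    def coverage_fraction(self) -> float:
        return len(self.flagged) / self.n_windows if self.n_windows else 0.0

    def sample_mask(self, n_samples: int, sampling_rate: float) -> np.ndarray:
        """Boolean mask, True where a sample falls inside a flagged window."""
        mask = np.zeros(n_samples, dtype=bool)
        w = int(round(self.window_s * sampling_rate))
        for idx in self.flagged:
            mask[idx * w : min((idx + 1) * w, n_samples)] = True
        return mask


@dataclass(frozen=True)
class BandPeak:
    """Subject-level band feature: peak power, frequency and location.

    ``power`` is in relative (baseline-corrected) units; ``peak_frequency``
    in Hz on the analysis grid; ``peak_location`` is an index into the
    source grid (or channel array for sensor-space analyses).
    """

    band: str
    power: float
    peak_frequency: float
    peak_location: int
    window: str  # "onset-offset" or "offset-plus-1s"
    mode: str  # "max" (ERS) or "min" (ERD)


@dataclass(frozen=True)
class SiciMeasure:
    """Short-interval intracortical inhibition for one protocol pair."""

    conditioned_mean: float
    unconditioned_mean: float
    ratio: float
    n_conditioned: int
    n_unconditioned: int


@dataclass(frozen=True)
class CorrelationResult:
    """Pearson correlation with default-prior Bayes factor."""

    r: float
    n_used: int
    removed_ids: tuple[int, ...]
    bf10: float
    category: str
    kappa: float


@dataclass(frozen=True)
class CorrelationComparison:
    """Fisher-z comparison of two correlation coefficients."""

    r1: float
    r2: float
    z: float
    p: float
    n: int
    n2: int | None
    mode: str
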