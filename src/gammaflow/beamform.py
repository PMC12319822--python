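"""Sensor normalisation and LCMV source projection.

The beamformer is the scalar (fixed-orientation) linearly constrained
minimum-variance filter: for a source with leadfield column ``l`` and
data covariance ``C``, the weight vector is

    w = (l' C^-1 l)^-1  l' C^-1

which passes unit gain at the target (``w . l = 1``) while minimising
projected variance.  The covariance inverse is taken on its top-``rank``
principal subspace (PCA rank reduction), with a spectral floor of
1e-12 x the largest eigenvalue.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from gammaflow.errors import InputError, NumericalError

__all__ = ["Leadfield", "eigen_normalize", "scale_leadfield", "covariance",
           "lcmv_weights", "project", "variance_map"]


@dataclass(frozen=True)
class Leadfield:
    """Forward model on a volumetric source grid.

    ``gain`` maps unit source activity to sensors, shape
    ``(n_sources, n_channels)`` — one fixed orientation per source.
    ``grid_coords`` holds source positions (n_sources, 3) in arbitrary
    length units; ``grid_shape`` and ``spacing`` describe the regular
    grid the sources sit on.
    """

    gain: np.ndarray
    grid_coords: np.ndarray
    grid_shape: tuple[int, int, int]
    spacing: float

    @property
    def n_sources(self) -> int:
        return self.gain.shape[0]

    @property
    def n_channels(self) -> int:
        return self.gain.shape[1]


def eigen_normalize(
    data: np.ndarray,
    channel_groups: np.ndarray,
    exclude: tuple[str, ...] = ("EMG",),
    tol: float = 1e-15,
) -> tuple[np.ndarray, dict[str, float]]:
    """Per-coil-type normalisation by the smallest covariance eigenvalue.

    For each channel group the eigenvalue decomposition of the group's
    channel covariance is computed and the group's data divided by the
    smallest eigenvalue, equalising scale across coil types with
    heterogeneous physical units.  Returns the rescaled data and the
    divisor per group.
    """
    groups = np.asarray(channel_groups, dtype=object)
    out = np.array(data, dtype=float, copy=True)
    scales: dict[str, float] = {}
    for g in dict.fromkeys(groups):
        if g in exclude:
            continue
        rows = np.flatnonzero(groups == g)
        if rows.size < 2:
            raise InputError(f"group {g!r} needs >= 2 channels to normalise")
        cov = np.cov(out[rows])
        lam_min = float(np.linalg.eigvalsh(cov)[0])
        if lam_min <= tol * max(float(np.linalg.eigvalsh(cov)[-1]), 1.0):
            raise NumericalError(
                f"group {g!r} covariance is rank deficient (smallest eigenvalue "
                f"{lam_min:.3g}); drop redundant channels or add regularisation"
            )
        out[rows] /= lam_min
        scales[g] = lam_min
    return out, scales


def scale_leadfield(lead: Leadfield, channel_groups: np.ndarray,
                    scales: dict[str, float]) -> Leadfield:
    """Apply the eigen-normalisation divisors to a leadfield.

    When the sensor data have been divided per coil type by
    :func:`eigen_normalize`, the forward model must be divided by the
    same factors so the beamformer's unit-gain constraint still points
    at the source's actual topography in the normalised data.
    """
    gain = lead.gain.copy()
    groups = np.asarray(channel_groups, dtype=object)
    for g, lam in scales.items():
        gain[:, groups == g] /= lam
    return Leadfield(gain=gain, grid_coords=lead.grid_coords,
                     grid_shape=lead.grid_shape, spacing=lead.spacing)


def covariance(data: np.ndarray, bad_mask: np.ndarray | None = None) -> np.ndarray:
    """Channel covariance across the whole (retained) time course."""
    x = data if bad_mask is None else data[:, ~bad_mask]
    if x.shape[1] < 2:
        raise InputError("not enough retained samples for a covariance")
    return np.cov(x)


def lcmv_weights(
    cov: np.ndarray,
    leadfield: Leadfield | np.ndarray,
    rank: int = 50,
    floor: float = 1e-12,
    tol: float = 1e-12,
) -> np.ndarray:
    """LCMV weights (sources x channels) with PCA rank reduction.

    ``rank`` larger than the number of channels is clipped with a
    warning.  A source whose projected power denominator falls below
    ``tol`` is flagged unresolvable (its weight row is set to NaN).
    """
    gain = leadfield.gain if isinstance(leadfield, Leadfield) else np.asarray(leadfield)
    cov = np.asarray(cov, dtype=float)
    n_ch = cov.shape[0]
    if cov.shape != (n_ch, n_ch) or gain.shape[1] != n_ch:
        raise InputError("covariance / leadfield channel dimensions disagree")
    if not np.allclose(cov, cov.T, atol=1e-10 * max(np.abs(cov).max(), 1.0)):
        raise InputError("covariance must be symmetric")
    if rank > n_ch:
        warnings.warn(f"rank {rank} exceeds {n_ch} channels; clipping", stacklevel=2)
        rank = n_ch
    lam, vec = np.linalg.eigh(cov)
    lam, vec = lam[::-1], vec[:, ::-1]
    keep = min(rank, int(np.sum(lam > floor * lam[0])))
    inv = (vec[:, :keep] / lam[:keep]) @ vec[:, :keep].T
    num = gain @ inv  # (sources x channels)
    denom = np.einsum("sc,sc->s", num, gain)
    weights = np.full_like(num, np.nan)
    ok = denom > tol * max(denom.max(), 0.0)  # relative: scale-invariant
    if not ok.any():
        raise NumericalError("no source has a resolvable LCMV denominator")
    weights[ok] = num[ok] / denom[ok, None]
    return weights


def project(epochs: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """Project sensor epochs to source space.

    ``epochs`` may be ``(trials, channels, samples)`` or a continuous
    ``(channels, samples)`` array; the channel axis is contracted with
    the weight matrix.
    """
    epochs = np.asarray(epochs, dtype=float)
    if epochs.ndim == 2:
        if weights.shape[1] != epochs.shape[0]:
            raise InputError("channel dimension mismatch")
        return weights @ epochs
    if epochs.ndim == 3:
        if weights.shape[1] != epochs.shape[1]:
            raise InputError("channel dimension mismatch")
        return np.einsum("sc,tcn->tsn", weights, epochs)
    raise InputError("epochs must be 2-D or 3-D")


def variance_map(
    data: np.ndarray,
    weights: np.ndarray,
    noise_normalize: bool = True,
) -> np.ndarray:
    """Source-space variance of continuous data under the given weights.

    With ``noise_normalize`` the variance is divided by the weight-vector
    norm squared (the unit-noise-gain / neural-activity-index form),
    cancelling the depth bias that otherwise inflates variance at
    weak-leadfield sources.
    """
    src = project(data, weights)
    var = src.var(axis=-1)
    if noise_normalize:
        var = var / np.einsum("sc,sc->s", weights, weights)
    return var
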