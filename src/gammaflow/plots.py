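"""Summary figures: time-frequency maps, peak heatmaps, power maps.

Thin matplotlib wrappers over the analysis containers; every function
returns the Axes so callers can compose panels.  The pipeline's report
writer uses them to emit per-band summaries.
"""

from __future__ import annotations

import numpy as np

from gammaflow.beamform import Leadfield
from gammaflow.spectral import TfPower

__all__ = ["plot_tf", "plot_peak_histogram", "plot_power_map"]


def plot_tf(tf: TfPower, location: int = 0, ax=None, title: str | None = None):
    """Trial-averaged time-frequency image at one location."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    img = tf.power[:, location].mean(axis=0)
    extent = [tf.times[0], tf.times[-1], tf.freqs[0], tf.freqs[-1]]
    vmax = np.abs(img).max() or 1.0
    m = ax.imshow(img, origin="lower", aspect="auto", extent=extent,
                  cmap="RdBu_r", vmin=-vmax, vmax=vmax)
    ax.axvline(0.0, color="k", lw=1)
    ax.set_xlabel("time re lock event (s)")
    ax.set_ylabel("frequency (Hz)")
    if title:
        ax.set_title(title)
    ax.figure.colorbar(m, ax=ax, label="relative power")
    return ax


def plot_peak_histogram(peak_freqs, band: str, ax=None):
    """Across-subject distribution of peak frequencies (1 Hz bins)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    freqs = np.asarray(peak_freqs, dtype=float)
    lo, hi = np.floor(freqs.min()) - 1, np.ceil(freqs.max()) + 1
    ax.hist(freqs, bins=np.arange(lo, hi + 1))
    ax.set_xlabel("peak frequency (Hz)")
    ax.set_ylabel("subjects")
    ax.set_title(band)
    return ax


def plot_power_map(values, lead: Leadfield, axis: int = 2, ax=None,
                   title: str | None = None):
    """Mid-volume slice of a per-source map on the grid."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    vol = np.asarray(values, dtype=float).reshape(lead.grid_shape)
    mid = vol.shape[axis] // 2
    img = np.take(vol, mid, axis=axis)
    m = ax.imshow(img.T, origin="lower", cmap="viridis")
    ax.set_xlabel("grid x")
    ax.set_ylabel("grid y")
    if title:
        ax.set_title(title)
    ax.figure.colorbar(m, ax=ax, label="power")
    return ax
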