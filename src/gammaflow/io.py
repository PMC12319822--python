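"""File formats: HDF5 recordings/leadfields, JSON masks, CSV tables.

Recordings are stored as HDF5 with datasets ``data`` (channels x
samples), ``channel_groups``, event columns ``event_sample`` /
``event_label`` and a ``sampling_rate`` attribute.  Trial and feature
tables are plain CSV via pandas; segment masks and ground truth are
JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from gammaflow.beamform import Leadfield
from gammaflow.containers import Recording, SegmentMask

__all__ = [
    "save_recording", "load_recording",
    "save_leadfield", "load_leadfield",
    "save_segment_mask", "load_segment_mask",
    "save_json", "load_json",
]


def save_recording(path: str | Path, recording: Recording) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=recording.data)
        f.create_dataset(
            "channel_groups",
            data=np.array([str(g) for g in recording.channel_groups], dtype="S"),
        )
        f.create_dataset("event_sample",
                         data=recording.events["sample"].to_numpy(dtype=np.int64))
        f.create_dataset(
            "event_label",
            data=np.array(recording.events["label"].astype(str), dtype="S"),
        )
        f.attrs["sampling_rate"] = recording.sampling_rate


def load_recording(path: str | Path) -> Recording:
    with h5py.File(path, "r") as f:
        events = pd.DataFrame({
            "sample": f["event_sample"][()].astype(int),
            "label": [s.decode() for s in f["event_label"][()]],
        })
        return Recording(
            data=f["data"][()],
            channel_groups=np.array([s.decode() for s in f["channel_groups"][()]],
                                    dtype=object),
            sampling_rate=float(f.attrs["sampling_rate"]),
            events=events,
        )


def save_leadfield(path: str | Path, lead: Leadfield) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("gain", data=lead.gain)
        f.create_dataset("grid_coords", data=lead.grid_coords)
        f.attrs["grid_shape"] = lead.grid_shape
        f.attrs["spacing"] = lead.spacing


def load_leadfield(path: str | Path) -> Leadfield:
    with h5py.File(path, "r") as f:
        return Leadfield(
            gain=f["gain"][()],
            grid_coords=f["grid_coords"][()],
            grid_shape=tuple(int(v) for v in f.attrs["grid_shape"]),
            spacing=float(f.attrs["spacing"]),
        )


def save_segment_mask(path: str | Path, mask: SegmentMask) -> None:
    Path(path).write_text(json.dumps({
        "window_s": mask.window_s,
        "flagged": list(mask.flagged),
        "n_windows": mask.n_windows,
    }))


def load_segment_mask(path: str | Path) -> SegmentMask:
    d = json.loads(Path(path).read_text())
    return SegmentMask(window_s=d["window_s"], flagged=tuple(d["flagged"]),
                       n_windows=d["n_windows"])


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serialisable: {type(obj)}")


def save_json(path: str | Path, payload: dict) -> None:
    Path(path).write_text(json.dumps(payload, indent=2, default=_jsonable))


def load_json(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())
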