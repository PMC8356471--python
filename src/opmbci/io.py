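"""HDF5 serialization of recordings and epoch sets.

Schema (one group hierarchy per container):

``/data``
    float64 array — channels x samples (recording) or epochs x channels
    x samples (epoch set)
``/`` attrs
    ``container`` ("recording" | "epochs"), ``fs_hz``, and ``t0_ms`` for
    epoch sets
``/channels``
    datasets ``names`` (utf-8 strings), ``kinds`` (utf-8 strings) and
    ``positions`` (n x 2 float)
``/events`` or ``/labels``
    one dataset per table column (numeric or utf-8 string)

Epoch sets can additionally be exported to FIF for interoperability with
standard MEG tooling when ``mne`` is installed.
"""

from __future__ import annotations

from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .containers import ContinuousRecording, EpochSet, SensorLayout

__all__ = ["save_recording", "load_recording", "save_epochs", "load_epochs",
           "epochs_to_mne"]

_STR = h5py.string_dtype(encoding="utf-8")


def _write_table(group: h5py.Group, table: pd.DataFrame) -> None:
    for col in table.columns:
        vals = table[col].to_numpy()
        if vals.dtype.kind in "OU":
            group.create_dataset(col, data=vals.astype(str), dtype=_STR)
        else:
            group.create_dataset(col, data=vals)
    group.attrs["columns"] = list(table.columns)


def _read_table(group: h5py.Group) -> pd.DataFrame:
    cols = list(group.attrs["columns"])
    out = {}
    for col in cols:
        vals = group[col][()]
        if vals.dtype.kind in "OS":
            vals = np.array([v.decode() if isinstance(v, bytes) else v for v in vals])
        out[col] = vals
    return pd.DataFrame(out, columns=cols)


def _write_layout(group: h5py.Group, layout: SensorLayout) -> None:
    group.create_dataset("names", data=list(layout.channel_names), dtype=_STR)
    group.create_dataset("kinds", data=list(layout.kinds), dtype=_STR)
    group.create_dataset("positions", data=layout.positions)


def _read_layout(group: h5py.Group) -> SensorLayout:
    names = tuple(n.decode() for n in group["names"][()])
    kinds = tuple(k.decode() for k in group["kinds"][()])
    return SensorLayout(names, kinds, group["positions"][()])


def save_recording(rec: ContinuousRecording, path: str | Path) -> None:
    with h5py.File(path, "w") as f:
        f.attrs["container"] = "recording"
        f.attrs["fs_hz"] = rec.fs_hz
        f.create_dataset("data", data=rec.data)
        _write_layout(f.create_group("channels"), rec.layout)
        _write_table(f.create_group("events"), rec.events)


def load_recording(path: str | Path) -> ContinuousRecording:
    with h5py.File(path, "r") as f:
        if f.attrs.get("container") != "recording":
            raise ValueError("file does not hold a continuous recording")
        return ContinuousRecording(
            data=f["data"][()],
            fs_hz=float(f.attrs["fs_hz"]),
            layout=_read_layout(f["channels"]),
            events=_read_table(f["events"]),
        )


def save_epochs(ep: EpochSet, path: str | Path) -> None:
    with h5py.File(path, "w") as f:
        f.attrs["container"] = "epochs"
        f.attrs["fs_hz"] = ep.fs_hz
        f.attrs["t0_ms"] = ep.t0_ms
        f.create_dataset("data", data=ep.data)
        _write_layout(f.create_group("channels"), ep.layout)
        _write_table(f.create_group("labels"), ep.labels)


def load_epochs(path: str | Path) -> EpochSet:
    with h5py.File(path, "r") as f:
        if f.attrs.get("container") != "epochs":
            raise ValueError("file does not hold an epoch set")
        return EpochSet(
            data=f["data"][()],
            fs_hz=float(f.attrs["fs_hz"]),
            t0_ms=float(f.attrs["t0_ms"]),
            labels=_read_table(f["labels"]),
            layout=_read_layout(f["channels"]),
        )


def epochs_to_mne(ep: EpochSet):
    """Convert an epoch set to :class:`mne.EpochsArray` (optional export).

    Magnetometer data (fT) is scaled to Tesla and EEG (uV) to Volt, the
    units mne expects; synthetic gradiometers are exported as
    magnetometer-type channels.
    """
    import mne  # deferred: interoperability extra, not a core dependency

    kind_map = {"mag": "mag", "grad": "mag", "eeg": "eeg"}
    info = mne.create_info(
        list(ep.layout.channel_names),
        ep.fs_hz,
        [kind_map[k] for k in ep.layout.kinds],
    )
    scale = np.array(
        [1e-15 if k in ("mag", "grad") else 1e-6 for k in ep.layout.kinds]
    )[None, :, None]
    return mne.EpochsArray(ep.data * scale, info, tmin=ep.t0_ms / 1000.0,
                           verbose="error")
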