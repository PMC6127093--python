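"""EpochSet container: trials × channels × samples tensors with montage.

Epochs are stimulus-locked EEG segments (by default −200…+998 ms at 500 Hz,
i.e. 600 samples over 64 channels) in microvolts.  The container carries the
time axis in milliseconds, channel names and 3-D montage positions, an
aligned per-trial label table, and round-trips through HDF5 (datasets
``/data``, ``/times``, ``/montage``; labels as a companion TSV aligned by
trial index).
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, replace

import h5py
import numpy as np
import pandas as pd


def load_montage() -> pd.DataFrame:
    """The packaged 64-channel standard-position table (channel, x, y, z)."""
    ref = importlib.resources.files("peersway.data").joinpath("montage64.csv")
    with importlib.resources.as_file(ref) as path:
        return pd.read_csv(path)


@dataclass
class EpochSet:
    """Per-participant epoch tensor plus metadata.

    ``data`` has shape (n_trials, n_channels, n_samples), ``times`` is in
    milliseconds, ``ch_pos`` is (n_channels, 3) in meters.  ``labels`` is an
    aligned trial table (row i describes trial i).
    """

    data: np.ndarray
    times: np.ndarray
    ch_names: list[str]
    ch_pos: np.ndarray
    labels: pd.DataFrame | None = None
    participant: str = "s01"
    sfreq: float = 500.0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("data must be trials × channels × samples")
        if self.data.shape[2] != self.times.size:
            raise ValueError("time axis length does not match data")
        if self.data.shape[1] != len(self.ch_names):
            raise ValueError("channel count does not match names")
        if self.ch_pos is not None and len(self.ch_pos) != len(self.ch_names):
            raise ValueError("channel count does not match montage")
        if self.labels is not None and len(self.labels) != self.data.shape[0]:
            raise ValueError("label table does not align with trials")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    def copy_with(self, **kwargs) -> "EpochSet":
        if "data" not in kwargs:
            kwargs["data"] = self.data.copy()
        return replace(self, **kwargs)

    def select(self, mask_or_index) -> "EpochSet":
        """Subset trials; the label table is subset in step."""
        idx = np.asarray(mask_or_index)
        data = self.data[idx]
        labels = None
        if self.labels is not None:
            labels = self.labels.iloc[np.flatnonzero(idx) if idx.dtype == bool else idx]
            labels = labels.reset_index(drop=True)
        return replace(self, data=data, labels=labels)

    def time_window_mask(self, start_ms: float, stop_ms: float) -> np.ndarray:
        """Boolean sample mask for the half-open window [start_ms, stop_ms)."""
        return (self.times >= start_ms) & (self.times < stop_ms)


def default_times(sfreq: float = 500.0, tmin_ms: float = -200.0,
                  tmax_ms: float = 1000.0) -> np.ndarray:
    """Sample axis in ms: [tmin, tmax) at the given rate (500 Hz → 600 samples)."""
    step = 1000.0 / sfreq
    return np.arange(tmin_ms, tmax_ms - step / 2, step)


def write_epochs(epochs: EpochSet, path, labels_path=None) -> None:
    """Write an EpochSet to HDF5; labels go to ``labels_path`` (TSV) if given."""
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=epochs.data.astype(np.float32))
        f.create_dataset("times", data=epochs.times)
        grp = f.create_group("montage")
        grp.create_dataset(
            "labels", data=np.array(epochs.ch_names, dtype=h5py.string_dtype())
        )
        grp.create_dataset("xyz", data=np.asarray(epochs.ch_pos, dtype=float))
        f.attrs["sfreq"] = epochs.sfreq
        f.attrs["participant"] = epochs.participant
    if labels_path is not None and epochs.labels is not None:
        epochs.labels.to_csv(labels_path, sep="\t", index=False)


def read_epochs(path, labels_path=None) -> EpochSet:
    with h5py.File(path, "r") as f:
        data = f["data"][()].astype(float)
        times = f["times"][()]
        ch_names = [s.decode() if isinstance(s, bytes) else s
                    for s in f["montage/labels"][()]]
        ch_pos = f["montage/xyz"][()]
        sfreq = float(f.attrs["sfreq"])
        participant = str(f.attrs.get("participant", "s01"))
    labels = None
    if labels_path is not None:
        labels = pd.read_csv(labels_path, sep="\t")
    return EpochSet(data=data, times=times, ch_names=ch_names, ch_pos=ch_pos,
                    labels=labels, participant=participant, sfreq=sfreq)
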