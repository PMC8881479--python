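"""Epoched-EEG container and its on-disk HDF5 layout.

`EpochSet` is the in-memory currency of the whole package: a trials x
channels x samples array of scalp potentials in microvolts, the sample times
relative to the alignment origin (the TMS pulse for evoked data, segment
onset for resting data), and one metadata record per trial.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import h5py
import numpy as np
import pandas as pd

META_COLUMNS = ("participant_id", "session_id", "domain", "state", "modality")


@dataclass
class EpochSet:
    """Labeled EEG epochs: ``data[trial, channel, sample]`` in microvolts."""

    data: np.ndarray
    srate_hz: float
    channel_labels: list[str]
    times_ms: np.ndarray
    trial_meta: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.times_ms = np.asarray(self.times_ms, dtype=float)
        if self.data.ndim != 3:
            raise ValueError(f"data must be trial x channel x sample, got shape {self.data.shape}")
        n_tr, n_ch, n_sm = self.data.shape
        if len(self.channel_labels) != n_ch:
            raise ValueError(f"{len(self.channel_labels)} channel labels for {n_ch} channels")
        if len(set(self.channel_labels)) != n_ch:
            raise ValueError("channel labels must be unique")
        if self.times_ms.shape != (n_sm,):
            raise ValueError(f"times_ms has {self.times_ms.size} entries for {n_sm} samples")
        if n_sm > 1 and not np.all(np.diff(self.times_ms) > 0):
            raise ValueError("times_ms must be strictly increasing")
        if self.srate_hz <= 0:
            raise ValueError("srate_hz must be positive")
        if len(self.trial_meta) != n_tr:
            raise ValueError(f"{len(self.trial_meta)} metadata rows for {n_tr} trials")
        missing = [c for c in META_COLUMNS if c not in self.trial_meta.columns]
        if missing:
            raise ValueError(f"trial_meta missing required fields: {missing}")
        self.trial_meta = self.trial_meta.reset_index(drop=True)
        for col in META_COLUMNS:
            bad = self.trial_meta[col].isna()
            if bad.any():
                idx = int(np.flatnonzero(bad.to_numpy())[0])
                raise ValueError(f"trial {idx} has missing {col!r}")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    def select_trials(self, index: np.ndarray) -> "EpochSet":
        """Return a copy restricted to the given trial indices / boolean mask."""
        index = np.asarray(index)
        return replace(
            self,
            data=self.data[index].copy(),
            trial_meta=self.trial_meta.iloc[np.flatnonzero(index) if index.dtype == bool else index],
        )

    def session_key(self) -> pd.Series:
        """participant_id/session_id composite key, one entry per trial."""
        m = self.trial_meta
        return m["participant_id"].astype(str) + "/" + m["session_id"].astype(str)


def write_container(path, epochs: EpochSet) -> None:
    """Write an EpochSet to the package HDF5 container (bit-exact round trip)."""
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=epochs.data, track_times=False)
        f.create_dataset("times_ms", data=epochs.times_ms, track_times=False)
        f.create_dataset("channels", data=np.array(epochs.channel_labels, dtype="S32"),
                         track_times=False)
        g = f.create_group("meta")
        for col in META_COLUMNS:
            g.create_dataset(col, data=epochs.trial_meta[col].astype(str).to_numpy(dtype="S64"),
                             track_times=False)
        f.attrs["srate_hz"] = float(epochs.srate_hz)


def read_container(path) -> EpochSet:
    """Read an EpochSet written by :func:`write_container`."""
    with h5py.File(path, "r") as f:
        meta = pd.DataFrame(
            {col: [v.decode() for v in f["meta"][col][()]] for col in META_COLUMNS}
        )
        return EpochSet(
            data=f["data"][()],
            srate_hz=float(f.attrs["srate_hz"]),
            channel_labels=[c.decode() for c in f["channels"][()]],
            times_ms=f["times_ms"][()],
            trial_meta=meta,
        )


def write_fif(path, epochs: EpochSet) -> None:
    """Export to an MNE epochs FIF file (metadata goes in a sidecar; the
    package container is the lossless format)."""
    import warnings

    import mne

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        info = mne.create_info(list(epochs.channel_labels), epochs.srate_hz, ch_types="eeg")
        ep = mne.EpochsArray(epochs.data * 1e-6, info,
                             tmin=epochs.times_ms[0] / 1000.0, verbose="error")
        ep.save(path, overwrite=True, verbose="error")


def read_sidecar(path) -> pd.DataFrame:
    """Read a trial-metadata sidecar table (CSV/TSV with a ``trial`` column)."""
    sep = "\t" if str(path).endswith((".tsv", ".tab")) else ","
    df = pd.read_csv(path, sep=sep)
    required = ["trial", *META_COLUMNS]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"sidecar missing required columns: {missing}")
    return df.sort_values("trial").reset_index(drop=True)
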