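"""Core data containers shared across the pipeline.

The central object is :class:`EpochSet`, a trials x channels x samples
voltage (or power) block with a time axis and per-trial metadata.  It is
deliberately minimal: a thin, validated wrapper around a numpy array and a
pandas DataFrame, with HDF5 round-tripping.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import h5py
import numpy as np
import pandas as pd

__all__ = ["EpochSet"]


@dataclass
class EpochSet:
    """Epoched multi-channel time series.

    Parameters
    ----------
    data : ndarray, shape (n_trials, n_channels, n_samples)
        Voltage (arbitrary units) or power per trial, channel and sample.
    srate : float
        Sampling rate in Hz.
    t0 : float
        Time of the first sample in seconds, relative to the trial's
        reference event (e.g. memory-cue onset).
    channel_labels : list of str
        One label per channel.
    trial_meta : pandas.DataFrame
        One row per trial.  Recognised columns: ``orientation`` (degrees,
        modulo 180), ``condition`` (free label), ``session`` and
        ``subject`` identifiers.  Extra columns pass through untouched.
    """

    data: np.ndarray
    srate: float
    t0: float
    channel_labels: list[str]
    trial_meta: pd.DataFrame = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError(
                f"data must be trials x channels x samples, got shape {self.data.shape}"
            )
        if not np.all(np.isfinite(self.data)):
            raise ValueError("data contains non-finite values")
        if self.srate <= 0:
            raise ValueError("srate must be positive")
        self.channel_labels = list(self.channel_labels)
        if len(self.channel_labels) != self.data.shape[1]:
            raise ValueError(
                f"{len(self.channel_labels)} channel labels for "
                f"{self.data.shape[1]} channels"
            )
        if self.trial_meta is None:
            self.trial_meta = pd.DataFrame(index=range(self.data.shape[0]))
        if len(self.trial_meta) != self.data.shape[0]:
            raise ValueError(
                f"{len(self.trial_meta)} metadata rows for {self.data.shape[0]} trials"
            )
        if "orientation" in self.trial_meta:
            ori = np.asarray(self.trial_meta["orientation"], dtype=float)
            if np.any((ori < 0) | (ori >= 180)):
                raise ValueError("orientations must lie in [0, 180)")

    # -- basic geometry ------------------------------------------------
    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    @property
    def times(self) -> np.ndarray:
        """Time axis in seconds."""
        return self.t0 + np.arange(self.n_samples) / self.srate

    def time_indices(self, window: tuple[float, float]) -> np.ndarray:
        """Sample indices whose times fall inside ``window`` (inclusive)."""
        start, stop = window
        if stop <= start:
            raise ValueError(f"empty window {window}")
        t = self.times
        idx = np.nonzero((t >= start - 1e-12) & (t <= stop + 1e-12))[0]
        if idx.size == 0:
            raise ValueError(f"window {window} outside epoch [{t[0]}, {t[-1]}]")
        return idx

    # -- selection -----------------------------------------------------
    def select_channels(self, labels: list[str]) -> "EpochSet":
        missing = [c for c in labels if c not in self.channel_labels]
        if missing:
            raise KeyError(
                f"unknown channels {missing}; available: {self.channel_labels}"
            )
        idx = [self.channel_labels.index(c) for c in labels]
        return replace(
            self,
            data=self.data[:, idx, :].copy(),
            channel_labels=list(labels),
            trial_meta=self.trial_meta.reset_index(drop=True),
        )

    def select_trials(self, mask) -> "EpochSet":
        mask = np.asarray(mask)
        return replace(
            self,
            data=self.data[mask].copy(),
            trial_meta=self.trial_meta.iloc[mask].reset_index(drop=True),
        )

    def sessions(self):
        """Iterate ``(session_id, EpochSet)`` pairs in sorted session order."""
        if "session" not in self.trial_meta:
            yield None, self
            return
        for sid in sorted(self.trial_meta["session"].unique()):
            yield sid, self.select_trials(
                (self.trial_meta["session"] == sid).to_numpy()
            )

    def copy(self) -> "EpochSet":
        return replace(
            self, data=self.data.copy(), trial_meta=self.trial_meta.copy()
        )

    # -- I/O -------------------------------------------------------------
    def to_hdf5(self, path) -> None:
        """Write ``/data``, ``/srate``, ``/t0``, ``/channels`` and a
        ``/trials`` group holding one dataset per metadata column."""
        with h5py.File(path, "w") as f:
            f.create_dataset("data", data=self.data)
            f["srate"] = float(self.srate)
            f["t0"] = float(self.t0)
            f.create_dataset(
                "channels",
                data=np.asarray(self.channel_labels, dtype=h5py.string_dtype()),
            )
            g = f.create_group("trials")
            for col in self.trial_meta.columns:
                vals = self.trial_meta[col].to_numpy()
                if vals.dtype == object:
                    vals = vals.astype(h5py.string_dtype())
                g.create_dataset(str(col), data=vals)

    @classmethod
    def from_hdf5(cls, path) -> "EpochSet":
        with h5py.File(path, "r") as f:
            data = f["data"][()]
            srate = float(f["srate"][()])
            t0 = float(f["t0"][()])
            channels = [
                c.decode() if isinstance(c, bytes) else str(c)
                for c in f["channels"][()]
            ]
            meta = {}
            for col in f["trials"]:
                vals = f["trials"][col][()]
                if vals.dtype.kind in "SO":
                    vals = np.array([v.decode() if isinstance(v, bytes) else v
                                     for v in vals])
                meta[col] = vals
        trial_meta = pd.DataFrame(meta) if meta else None
        return cls(data, srate, t0, channels, trial_meta)

    def meta_to_csv(self, path) -> None:
        self.trial_meta.to_csv(path, index=False)
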