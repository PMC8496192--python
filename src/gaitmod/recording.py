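"""Multichannel recording container and HDF5 session I/O.

A :class:`Recording` is the common currency of the package: a dense
``(n_channels, n_samples)`` float array sampled uniformly at ``fs`` Hz, with
unique per-channel labels and a *kind* tag per channel (``lfp``, ``eeg``,
``force`` or ``accel``) that downstream stages use to pick default filter
chains and channel groups.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import h5py
import numpy as np

CHANNEL_KINDS = ("lfp", "eeg", "force", "accel")


@dataclass
class Recording:
    """Uniformly sampled multichannel time series.

    Parameters
    ----------
    signals : ndarray, shape (n_channels, n_samples)
        Channel data in volts (or native sensor units).
    fs : float
        Sampling rate in Hz, shared by all channels.
    labels : list of str
        Unique channel names.
    kinds : list of str
        Per-channel tag, one of ``{"lfp", "eeg", "force", "accel"}``.
    """

    signals: np.ndarray
    fs: float
    labels: list[str] = field(default_factory=list)
    kinds: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.signals = np.atleast_2d(np.asarray(self.signals, dtype=float))
        if self.fs <= 0:
            raise ValueError(f"fs must be positive, got {self.fs}")
        n = self.signals.shape[0]
        if not self.labels:
            self.labels = [f"ch{i}" for i in range(n)]
        if not self.kinds:
            self.kinds = ["lfp"] * n
        self.labels = list(self.labels)
        self.kinds = list(self.kinds)
        if len(self.labels) != n or len(self.kinds) != n:
            raise ValueError(
                "labels/kinds length does not match number of channels"
            )
        if len(set(self.labels)) != n:
            raise ValueError("channel labels must be unique")
        bad = sorted(set(self.kinds) - set(CHANNEL_KINDS))
        if bad:
            raise ValueError(f"unknown channel kinds: {bad}")
        if np.isnan(self.signals).any():
            raise ValueError("signals contain NaNs")

    # -- convenience -------------------------------------------------------

    @property
    def n_channels(self) -> int:
        return self.signals.shape[0]

    @property
    def n_samples(self) -> int:
        return self.signals.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.fs

    def index(self, label: str) -> int:
        try:
            return self.labels.index(label)
        except ValueError:
            raise KeyError(
                f"channel {label!r} not found; available: {self.labels}"
            ) from None

    def get(self, label: str) -> np.ndarray:
        """Return one channel's samples by label."""
        return self.signals[self.index(label)]

    def pick(self, labels=None, kind: str | None = None) -> "Recording":
        """Sub-recording with the given labels and/or a single kind."""
        idx = range(self.n_channels)
        if labels is not None:
            idx = [self.index(lab) for lab in labels]
        if kind is not None:
            idx = [i for i in idx if self.kinds[i] == kind]
        idx = list(idx)
        if not idx:
            raise ValueError("selection matches no channels")
        return replace(
            self,
            signals=self.signals[idx].copy(),
            labels=[self.labels[i] for i in idx],
            kinds=[self.kinds[i] for i in idx],
        )


def save_recording(group: h5py.Group, rec: Recording) -> None:
    """Write a Recording into an open HDF5 group (datasets signals/labels/kinds/fs)."""
    group.create_dataset("signals", data=rec.signals)
    group.create_dataset(
        "labels", data=np.array(rec.labels, dtype=h5py.string_dtype())
    )
    group.create_dataset(
        "kinds", data=np.array(rec.kinds, dtype=h5py.string_dtype())
    )
    group.attrs["fs"] = float(rec.fs)


def load_recording(group: h5py.Group) -> Recording:
    return Recording(
        signals=np.asarray(group["signals"]),
        fs=float(group.attrs["fs"]),
        labels=[s.decode() if isinstance(s, bytes) else str(s) for s in group["labels"][()]],
        kinds=[s.decode() if isinstance(s, bytes) else str(s) for s in group["kinds"][()]],
    )
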