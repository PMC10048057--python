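"""In-memory containers for continuous recordings and epoched trials.

``RawRecording`` holds a continuous multichannel EEG segment in microvolts
with its event markers; ``TrialSet`` holds epoched trials as a
(trial x channel x time) array with integer class labels.  Both round-trip
through a simple HDF5 layout (``/signals`` + ``/events`` for recordings,
``/trials`` + ``/labels`` for trial sets, metadata as attributes).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import h5py
import numpy as np

#: class encoding used throughout: small=0, medium=1, large=2
CLASS_NAMES: tuple[str, ...] = ("small", "medium", "large")


@dataclass
class RawRecording:
    """Continuous multichannel EEG.

    Parameters
    ----------
    signals : ndarray, shape (n_channels, n_samples)
        Signal in microvolts.
    fs : float
        Sampling rate in Hz.
    channel_labels : list of str
        One unique label per row of ``signals``.
    events : ndarray, shape (n_events, 2)
        Columns ``(onset_sample, class_label)``; onsets mark the start of
        the motor-imagery period of each trial, sorted ascending.
    """

    signals: np.ndarray
    fs: float
    channel_labels: list[str]
    events: np.ndarray = field(default_factory=lambda: np.empty((0, 2), dtype=np.int64))

    def __post_init__(self) -> None:
        self.signals = np.asarray(self.signals)
        if self.signals.ndim != 2:
            raise ValueError("signals must be (n_channels, n_samples)")
        self.channel_labels = [str(c) for c in self.channel_labels]
        if len(self.channel_labels) != self.signals.shape[0]:
            raise ValueError("one label per signal row required")
        if len(set(self.channel_labels)) != len(self.channel_labels):
            raise ValueError("channel labels must be unique")
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        self.events = np.asarray(self.events, dtype=np.int64).reshape(-1, 2)
        if self.events.size:
            onsets = self.events[:, 0]
            if np.any(np.diff(onsets) < 0):
                raise ValueError("events must be sorted by onset")
            if onsets.min() < 0 or onsets.max() >= self.n_samples:
                raise ValueError("event onsets outside signal bounds")

    @property
    def n_channels(self) -> int:
        return self.signals.shape[0]

    @property
    def n_samples(self) -> int:
        return self.signals.shape[1]

    @property
    def duration(self) -> float:
        """Length of the recording in seconds."""
        return self.n_samples / self.fs

    def channel_index(self, label: str) -> int:
        try:
            return self.channel_labels.index(label)
        except ValueError:
            raise KeyError(f"channel {label!r} not in recording") from None

    def copy_with(self, **kwargs) -> "RawRecording":
        """Return a shallow-copied recording with fields replaced."""
        return replace(self, **kwargs)

    # -- HDF5 round trip ---------------------------------------------------

    def to_hdf5(self, path) -> None:
        with h5py.File(path, "w") as f:
            f.create_dataset("signals", data=self.signals)
            f.create_dataset("events", data=self.events)
            f.attrs["fs"] = float(self.fs)
            f.attrs["channel_labels"] = list(self.channel_labels)
            f.attrs["container"] = "raw_recording"

    @classmethod
    def from_hdf5(cls, path) -> "RawRecording":
        with h5py.File(path, "r") as f:
            if f.attrs.get("container") != "raw_recording":
                raise ValueError(f"{path} is not a raw-recording container")
            return cls(
                signals=f["signals"][()],
                fs=float(f.attrs["fs"]),
                channel_labels=[c.decode() if isinstance(c, bytes) else str(c)
                                for c in f.attrs["channel_labels"]],
                events=f["events"][()],
            )


@dataclass
class TrialSet:
    """Epoched trials as a (trial x channel x time) array.

    ``window`` is the epoch extent in seconds relative to the motor-imagery
    onset (onset = 0 s), e.g. ``(0.0, 6.0)`` for the classification window
    or ``(-1.0, 6.0)`` for spectral analysis with a pre-onset baseline.
    """

    data: np.ndarray
    labels: np.ndarray
    fs: float
    window: tuple[float, float]
    channel_labels: list[str]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError("data must be (trial, channel, time)")
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if self.labels.shape != (self.data.shape[0],):
            raise ValueError("one label per trial required")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("trial data contains non-finite values")
        self.channel_labels = [str(c) for c in self.channel_labels]
        if len(self.channel_labels) != self.data.shape[1]:
            raise ValueError("one label per channel required")
        self.window = (float(self.window[0]), float(self.window[1]))

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_times(self) -> int:
        return self.data.shape[2]

    @property
    def times(self) -> np.ndarray:
        """Per-sample times in seconds relative to MI onset."""
        return self.window[0] + np.arange(self.n_times) / self.fs

    def channel_index(self, label: str) -> int:
        try:
            return self.channel_labels.index(label)
        except ValueError:
            raise KeyError(f"channel {label!r} not in trial set") from None

    def select_class(self, label: int) -> "TrialSet":
        keep = self.labels == label
        return TrialSet(self.data[keep], self.labels[keep], self.fs,
                        self.window, list(self.channel_labels))

    def select_channels(self, labels) -> "TrialSet":
        idx = [self.channel_index(l) for l in labels]
        return TrialSet(self.data[:, idx], self.labels, self.fs,
                        self.window, [self.channel_labels[i] for i in idx])

    # -- HDF5 round trip ---------------------------------------------------

    def to_hdf5(self, path) -> None:
        with h5py.File(path, "w") as f:
            f.create_dataset("trials", data=self.data)
            f.create_dataset("labels", data=self.labels)
            f.attrs["fs"] = float(self.fs)
            f.attrs["window"] = list(self.window)
            f.attrs["channel_labels"] = list(self.channel_labels)
            f.attrs["container"] = "trial_set"

    @classmethod
    def from_hdf5(cls, path) -> "TrialSet":
        with h5py.File(path, "r") as f:
            if f.attrs.get("container") != "trial_set":
                raise ValueError(f"{path} is not a trial-set container")
            return cls(
                data=f["trials"][()],
                labels=f["labels"][()],
                fs=float(f.attrs["fs"]),
                window=tuple(f.attrs["window"]),
                channel_labels=[c.decode() if isinstance(c, bytes) else str(c)
                                for c in f.attrs["channel_labels"]],
            )
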