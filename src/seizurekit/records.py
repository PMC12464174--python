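"""In-memory containers for EEG recordings and windowed datasets.

An :class:`EEGRecord` holds a ``channels x samples`` signal matrix together
with its sampling rate, channel labels and optional interval annotations
(seconds, half-open, with a string label).  A :class:`WindowedDataset` is the
unit that the feature and training stages consume: a stack of equally shaped
windows with integer class labels and provenance back to the source record.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["EEGRecord", "WindowedDataset", "Annotation"]


@dataclass(frozen=True)
class Annotation:
    """A labelled interval ``[start_s, end_s)`` in seconds."""

    start_s: float
    end_s: float
    label: str

    def __post_init__(self) -> None:
        if self.end_s < self.start_s:
            raise ValueError(f"annotation ends before it starts: {self}")


@dataclass
class EEGRecord:
    """A multi- or single-channel EEG signal with metadata.

    Parameters
    ----------
    data
        ``(n_channels, n_samples)`` float array, microvolt-scale (units are
        carried but not enforced).
    fs
        Sampling rate in Hz, strictly positive.
    channel_labels
        One label per channel; generated as ``ch00 ...`` when omitted.
    record_id
        Free-form identifier used for provenance.
    annotations
        Optional labelled intervals, each within ``[0, duration]``.
    """

    data: np.ndarray
    fs: float
    channel_labels: list[str] = field(default_factory=list)
    record_id: str = ""
    annotations: list[Annotation] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.atleast_2d(np.asarray(self.data, dtype=np.float64))
        if self.data.ndim != 2:
            raise ValueError("data must be a channels x samples matrix")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("data contains non-finite values")
        if self.fs <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        if not self.channel_labels:
            self.channel_labels = [f"ch{i:02d}" for i in range(self.n_channels)]
        if len(self.channel_labels) != self.n_channels:
            raise ValueError(
                f"{len(self.channel_labels)} labels for {self.n_channels} channels"
            )
        for ann in self.annotations:
            if ann.start_s < 0 or ann.end_s > self.duration + 1e-9:
                raise ValueError(f"annotation {ann} outside [0, {self.duration:.3f}]")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        """Record length in seconds."""
        return self.n_samples / self.fs


@dataclass
class WindowedDataset:
    """Fixed-length windows with integer class labels.

    ``windows`` has shape ``(n_windows, n_channels, window_samples)``;
    ``labels[i]`` indexes ``class_names``; ``provenance[i]`` is the
    ``(record_id, start_sample)`` pair the window was cut from.
    """

    windows: np.ndarray
    labels: np.ndarray
    class_names: list[str]
    provenance: list[tuple[str, int]]

    def __post_init__(self) -> None:
        self.windows = np.asarray(self.windows, dtype=np.float64)
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if self.windows.ndim != 3:
            raise ValueError("windows must be (n_windows, n_channels, n_samples)")
        n = self.windows.shape[0]
        if self.labels.shape != (n,) or len(self.provenance) != n:
            raise ValueError("windows, labels and provenance lengths disagree")
        k = len(self.class_names)
        if n and (self.labels.min() < 0 or self.labels.max() >= k):
            raise ValueError(f"labels outside [0, {k})")

    def __len__(self) -> int:
        return self.windows.shape[0]

    @property
    def n_classes(self) -> int:
        return len(self.class_names)

    def class_counts(self) -> np.ndarray:
        return np.bincount(self.labels, minlength=self.n_classes)

    def subset(self, idx: np.ndarray) -> "WindowedDataset":
        idx = np.asarray(idx)
        return WindowedDataset(
            windows=self.windows[idx],
            labels=self.labels[idx],
            class_names=list(self.class_names),
            provenance=[self.provenance[int(i)] for i in idx],
        )
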