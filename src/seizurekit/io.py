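"""Readers, writers and window/normalize transforms for EEG sources.

Two on-disk formats are supported: Bonn-style plain text (one sample per
line, single channel) and 16-bit EDF.  EDF reading goes through mne's native
reader; writing uses a minimal EDF emitter sufficient for round-trip tests
and synthetic exports (single data record, linear 16-bit quantization).

Windowing cuts fixed-length, optionally overlapping windows and labels each
one from interval annotations by majority overlap; normalization z-scores
each channel of a window independently (population standard deviation), the
per-window zero-mean unit-variance convention the model expects.
"""

from __future__ import annotations

import logging
from fractions import Fraction
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
from scipy import signal as sps

from .records import Annotation, EEGRecord, WindowedDataset

__all__ = [
    "read_bonn_segment",
    "write_bonn_segment",
    "read_edf",
    "write_edf",
    "select_leading_channels",
    "resample_record",
    "window_record",
    "normalize_window",
    "normalize_dataset",
    "majority_labeler",
    "edf_quantization_bound",
]

logger = logging.getLogger(__name__)

BONN_FS = 173.61


# ---------------------------------------------------------------- Bonn text

def read_bonn_segment(path: str | Path, fs: float = BONN_FS) -> EEGRecord:
    """Read a single-channel plain-text segment (one sample per line).

    Tolerates surrounding whitespace and integer or float literals; blank
    lines are skipped.  Raises ``ValueError`` naming the offending line on a
    parse failure and on an empty file.
    """
    path = Path(path)
    values: list[float] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            s = line.strip()
            if not s:
                continue
            try:
                values.append(float(s))
            except ValueError:
                raise ValueError(
                    f"{path}: line {lineno}: cannot parse {s!r} as a number"
                ) from None
    if not values:
        raise ValueError(f"{path}: empty segment file")
    return EEGRecord(
        data=np.asarray(values)[None, :], fs=fs, record_id=path.stem
    )


def write_bonn_segment(rec: EEGRecord, path: str | Path, fmt: str = "%.6g") -> None:
    """Write a single-channel record as one sample per line."""
    if rec.n_channels != 1:
        raise ValueError(f"Bonn text format is single-channel, got {rec.n_channels}")
    np.savetxt(path, rec.data[0], fmt=fmt)


# ---------------------------------------------------------------------- EDF

def read_edf(path: str | Path) -> EEGRecord:
    """Load every signal channel of an EDF file via mne.

    Channels recorded at heterogeneous rates are resampled to the maximum
    rate before stacking (mne does this on load); labels are preserved
    verbatim.  Raises ``ValueError`` on malformed headers or zero channels.
    """
    path = Path(path)
    try:
        raw = mne_read(path)
    except Exception as exc:  # mne raises several types on bad headers
        raise ValueError(f"{path}: cannot read EDF: {exc}") from exc
    data = raw.get_data()
    if data.shape[0] == 0:
        raise ValueError(f"{path}: EDF file contains no signal channels")
    return EEGRecord(
        data=data * 1e6,  # mne loads volts; keep microvolt scale
        fs=float(raw.info["sfreq"]),
        channel_labels=list(raw.ch_names),
        record_id=path.stem,
    )


def mne_read(path: Path):
    import mne

    return mne.io.read_raw_edf(str(path), preload=True, verbose="error")


def write_edf(rec: EEGRecord, path: str | Path) -> None:
    """Write a record as a minimal one-data-record 16-bit EDF file.

    Amplitudes are linearly quantized per channel into the signed 16-bit
    range between the channel's physical min/max, the standard EDF scheme;
    round-trip error is bounded by half a quantization step.
    """
    path = Path(path)
    n_ch, n_samp = rec.n_channels, rec.n_samples
    duration = n_samp / rec.fs

    phys_min = rec.data.min(axis=1)
    phys_max = rec.data.max(axis=1)
    # Guard degenerate (constant) channels against a zero quantization span.
    flat = phys_max - phys_min <= 0
    phys_max = np.where(flat, phys_min + 1.0, phys_max)
    dig_min, dig_max = -32768, 32767

    def pad(text: str, width: int) -> bytes:
        b = text.encode("ascii")
        if len(b) > width:
            raise ValueError(f"EDF header field too long: {text!r}")
        return b.ljust(width)

    header = b"".join(
        [
            pad("0", 8),  # version
            pad("X X X X", 80),  # patient id (anonymous)
            pad("Startdate X X X X", 80),  # recording id
            pad("01.01.00", 8),
            pad("00.00.00", 8),
            pad(str(256 * (1 + n_ch)), 8),  # header bytes
            pad("", 44),
            pad("1", 8),  # number of data records
            pad(f"{duration:.6f}"[:8].rstrip("."), 8),
            pad(str(n_ch), 4),
        ]
    )
    fields: list[bytes] = []
    fields.append(b"".join(pad(lbl[:16], 16) for lbl in rec.channel_labels))
    fields.append(b"".join(pad("", 80) for _ in range(n_ch)))  # transducer
    fields.append(b"".join(pad("uV", 8) for _ in range(n_ch)))
    fields.append(b"".join(pad(f"{v:.7g}"[:8], 8) for v in phys_min))
    fields.append(b"".join(pad(f"{v:.7g}"[:8], 8) for v in phys_max))
    fields.append(b"".join(pad(str(dig_min), 8) for _ in range(n_ch)))
    fields.append(b"".join(pad(str(dig_max), 8) for _ in range(n_ch)))
    fields.append(b"".join(pad("", 80) for _ in range(n_ch)))  # prefiltering
    fields.append(b"".join(pad(str(n_samp), 8) for _ in range(n_ch)))
    fields.append(b"".join(pad("", 32) for _ in range(n_ch)))

    # Re-read the physical ranges exactly as the 8-char header strings a
    # reader will parse, so quantization is consistent with the header.
    pmin = np.array([float(f"{v:.7g}"[:8]) for v in phys_min])
    pmax = np.array([float(f"{v:.7g}"[:8]) for v in phys_max])
    gain = (pmax - pmin) / (dig_max - dig_min)
    digital = np.rint((rec.data - pmin[:, None]) / gain[:, None] + dig_min)
    digital = np.clip(digital, dig_min, dig_max).astype("<i2")

    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(b"".join(fields))
        fh.write(digital.tobytes())  # channel-sequential within the record
    _check_edf_size(path, n_ch, n_samp)


def _check_edf_size(path: Path, n_ch: int, n_samp: int) -> None:
    expected = 256 * (1 + n_ch) + 2 * n_ch * n_samp
    actual = path.stat().st_size
    if actual != expected:
        raise IOError(f"{path}: wrote {actual} bytes, expected {expected}")


def edf_quantization_bound(rec: EEGRecord) -> np.ndarray:
    """Per-channel worst-case amplitude error of a 16-bit EDF round trip."""
    span = rec.data.max(axis=1) - rec.data.min(axis=1)
    span = np.where(span <= 0, 1.0, span)
    return span / 65535.0  # half a step either side of rounding


# ------------------------------------------------------------- transforms

def select_leading_channels(rec: EEGRecord, k: int) -> EEGRecord:
    """Keep the first ``k`` channels in original order (e.g. the first 22
    channels of a CHB-MIT-style montage)."""
    if k < 1 or k > rec.n_channels:
        raise IndexError(f"k={k} outside [1, {rec.n_channels}]")
    return EEGRecord(
        data=rec.data[:k].copy(),
        fs=rec.fs,
        channel_labels=rec.channel_labels[:k],
        record_id=rec.record_id,
        annotations=list(rec.annotations),
    )


def resample_record(rec: EEGRecord, target_fs: float) -> EEGRecord:
    """Band-limited (polyphase) resampling of every channel to ``target_fs``.

    The new length is ``round(n * target_fs / fs)``.  Identity when the rate
    already matches.
    """
    if target_fs <= 0:
        raise ValueError(f"target_fs must be positive, got {target_fs}")
    if target_fs == rec.fs:
        return rec
    ratio = Fraction(target_fs / rec.fs).limit_denominator(10_000)
    out = sps.resample_poly(rec.data, ratio.numerator, ratio.denominator, axis=1)
    n_target = int(round(rec.n_samples * target_fs / rec.fs))
    if out.shape[1] > n_target:
        out = out[:, :n_target]
    elif out.shape[1] < n_target:
        out = np.pad(out, ((0, 0), (0, n_target - out.shape[1])), mode="edge")
    return EEGRecord(
        data=out,
        fs=target_fs,
        channel_labels=list(rec.channel_labels),
        record_id=rec.record_id,
        annotations=list(rec.annotations),
    )


def majority_labeler(
    class_names: Sequence[str] = ("background", "seizure"),
) -> Callable[[list[Annotation], int, int, float], int]:
    """Window labeler assigning the class with the largest annotated overlap.

    Samples not covered by any annotation count toward class 0 (background).
    Ties break toward the *higher* class index — for the binary case, toward
    seizure, the safety-biased choice for a detector.
    """
    name_to_idx = {name: i for i, name in enumerate(class_names)}

    def labeler(
        annotations: list[Annotation], start: int, stop: int, fs: float
    ) -> int:
        overlap = np.zeros(len(class_names))
        covered = 0.0
        for ann in annotations:
            a = max(start, int(np.floor(ann.start_s * fs)))
            b = min(stop, int(np.floor(ann.end_s * fs)))
            if b > a:
                if ann.label not in name_to_idx:
                    raise KeyError(f"annotation label {ann.label!r} not in classes")
                overlap[name_to_idx[ann.label]] += b - a
                covered += b - a
        overlap[0] += (stop - start) - covered
        best = overlap.max()
        return int(np.max(np.flatnonzero(overlap == best)))

    return labeler


def window_record(
    rec: EEGRecord,
    window_samples: int,
    overlap_samples: int = 0,
    labeler: Callable[[list[Annotation], int, int, float], int] | None = None,
    class_names: Sequence[str] = ("background", "seizure"),
    normalize: bool = False,
) -> WindowedDataset:
    """Cut fixed-length windows from a record.

    With hop ``h = window_samples - overlap_samples`` the record yields
    ``floor((n - window_samples) / h) + 1`` windows; any trailing partial
    window is dropped.  Window ``i`` covers samples
    ``[i*h, i*h + window_samples)`` and is labelled by ``labeler`` (majority
    annotation overlap by default).
    """
    if window_samples < 1 or window_samples > rec.n_samples:
        raise ValueError(
            f"window_samples={window_samples} outside [1, {rec.n_samples}]"
        )
    if overlap_samples < 0 or overlap_samples >= window_samples:
        raise ValueError(
            f"overlap ({overlap_samples}) must be in [0, window_samples)"
        )
    if labeler is None:
        labeler = majority_labeler(class_names)
    hop = window_samples - overlap_samples
    n_windows = (rec.n_samples - window_samples) // hop + 1

    windows = np.empty((n_windows, rec.n_channels, window_samples))
    labels = np.empty(n_windows, dtype=np.int64)
    provenance: list[tuple[str, int]] = []
    for i in range(n_windows):
        start = i * hop
        w = rec.data[:, start : start + window_samples]
        windows[i] = normalize_window(w) if normalize else w
        labels[i] = labeler(rec.annotations, start, start + window_samples, rec.fs)
        provenance.append((rec.record_id, start))

    return WindowedDataset(
        windows=windows,
        labels=labels,
        class_names=list(class_names),
        provenance=provenance,
    )


def normalize_window(w: np.ndarray) -> np.ndarray:
    """Z-score each channel: zero mean, unit population (ddof=0) variance.

    Constant channels cannot be scaled and map to zeros (logged).  The
    transform is idempotent and shape-preserving.
    """
    w = np.atleast_2d(np.asarray(w, dtype=np.float64))
    if not np.all(np.isfinite(w)):
        raise ValueError("window contains non-finite values")
    mean = w.mean(axis=1, keepdims=True)
    sd = w.std(axis=1, keepdims=True)
    # Channels constant up to floating-point rounding of the mean count as
    # constant, otherwise re-normalizing a (numerically) flat channel would
    # blow rounding noise up to +/-1.
    flat = sd[:, 0] <= 1e-12 * np.maximum(np.abs(mean[:, 0]), 1.0)
    if np.any(flat):
        logger.warning(
            "normalize_window: %d constant channel(s) mapped to zeros",
            int(flat.sum()),
        )
    sd = np.where(flat[:, None], 1.0, sd)
    out = (w - mean) / sd
    out[flat] = 0.0
    return out


def normalize_dataset(ds: WindowedDataset) -> WindowedDataset:
    """Apply :func:`normalize_window` to every window (stateless, so safe to
    run before any train/test split)."""
    windows = np.stack([normalize_window(w) for w in ds.windows])
    return WindowedDataset(
        windows=windows,
        labels=ds.labels.copy(),
        class_names=list(ds.class_names),
        provenance=list(ds.provenance),
    )
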