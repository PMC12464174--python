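"""Per-channel DWT feature vectors plus classical baseline features.

The model input is built by decomposing each channel with an L-level
discrete wavelet transform and concatenating the coefficient arrays
coarse-to-fine — ``[A_L, D_L, ..., D_1]`` — then concatenating channels.
With the default Haar (db1) wavelet at level 3 a 4097-sample channel yields
513 + 513 + 1025 + 2049 = 4100 coefficients, and at 256 Hz the four bands
nominally cover 0-16 Hz (A3, delta--alpha), 16-32 Hz (D3, beta),
32-64 Hz (D2, gamma) and 64-128 Hz (D1, high gamma).

Classical comparison features: per-channel time-domain statistics
(mean, SD, RMS) and Welch-PSD spectral summaries (mean and median
frequency).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pywt
from scipy import signal as sps

__all__ = [
    "WaveletConfig",
    "WaveletFeatures",
    "dwt_decompose",
    "concat_features",
    "coeff_length",
    "time_domain_features",
    "freq_domain_features",
]


@dataclass(frozen=True)
class WaveletConfig:
    """Wavelet name, decomposition level and border extension mode.

    ``db1`` (Haar, filter length 2) at level 3 is the default: it is the
    only Daubechies member whose coefficient count for a 4097-sample channel
    equals the model's printed input length of 4100.  The border mode
    changes coefficient values but not lengths.
    """

    wavelet_name: str = "db1"
    level: int = 3
    mode: str = "symmetric"

    def __post_init__(self) -> None:
        if self.level < 1:
            raise ValueError(f"level must be >= 1, got {self.level}")
        try:
            pywt.Wavelet(self.wavelet_name)
        except ValueError:
            raise ValueError(f"unknown wavelet {self.wavelet_name!r}") from None

    @property
    def filter_length(self) -> int:
        return pywt.Wavelet(self.wavelet_name).dec_len

    def band_labels(self) -> list[str]:
        """Coefficient-array labels coarse to fine, e.g. A3, D3, D2, D1."""
        L = self.level
        return [f"A{L}"] + [f"D{j}" for j in range(L, 0, -1)]

    def band_ranges(self, fs: float) -> list[tuple[float, float]]:
        """Nominal frequency span of each band at sampling rate ``fs``.

        Each decimation halves the band: A_L covers 0 to fs/2^(L+1), D_j
        covers fs/2^(j+1) to fs/2^j.
        """
        L = self.level
        ranges = [(0.0, fs / 2 ** (L + 1))]
        for j in range(L, 0, -1):
            ranges.append((fs / 2 ** (j + 1), fs / 2**j))
        return ranges


@dataclass
class WaveletFeatures:
    """Decomposition of one window: per-channel coefficient arrays, the
    flat concatenated vector, and a map from every index of that vector to
    its (channel, band label, band Hz range)."""

    per_channel: list[dict[str, np.ndarray]]
    concat: np.ndarray
    band_map: list[tuple[int, str, tuple[float, float]]] = field(repr=False)

    @property
    def n_channels(self) -> int:
        return len(self.per_channel)


def coeff_length(
    n: int, filter_len: int, level: int, mode: str = "symmetric"
) -> list[int]:
    """Closed-form coefficient lengths ``[A_L, D_L, ..., D_1]``.

    With border extension (symmetric and friends) each analysis step maps a
    length-L signal to floor((L + f - 1) / 2) coefficients (filter length f,
    decimation by 2); periodization yields ceil(L / 2) regardless of f.
    Matches :func:`dwt_decompose` output lengths exactly.
    """
    if filter_len < 2:
        raise ValueError(f"filter length must be >= 2, got {filter_len}")
    if n < filter_len:
        raise ValueError(f"signal length {n} shorter than filter {filter_len}")
    detail_lengths: list[int] = []
    length = n
    for lvl in range(level):
        if length < filter_len:
            raise ValueError(
                f"level {lvl + 1} infeasible: length {length} < filter {filter_len}"
            )
        if mode == "periodization":
            length = (length + 1) // 2
        else:
            length = (length + filter_len - 1) // 2
        detail_lengths.append(length)
    # Coarse-to-fine: approximation (same length as deepest detail) first.
    return [detail_lengths[-1]] + detail_lengths[::-1]


def dwt_decompose(x: np.ndarray, cfg: WaveletConfig | None = None) -> dict[str, np.ndarray]:
    """L-level DWT of a 1D signal, returned as ``{A_L, D_L, ..., D_1}``.

    Uses the pyramid algorithm (low/high-pass filtering and decimation by 2
    at each level, recursing on the approximation).  For orthogonal wavelets
    the transform conserves energy exactly whenever no border extension is
    needed (every intermediate length even); border padding perturbs it.
    """
    cfg = cfg or WaveletConfig()
    x = np.asarray(x, dtype=np.float64)
    if x.ndim != 1:
        raise ValueError(f"expected a 1D signal, got shape {x.shape}")
    expected = coeff_length(len(x), cfg.filter_length, cfg.level, cfg.mode)  # validates
    coeffs = pywt.wavedec(x, cfg.wavelet_name, mode=cfg.mode, level=cfg.level)
    labels = cfg.band_labels()
    out = {lab: np.asarray(c) for lab, c in zip(labels, coeffs)}
    got = [len(out[lab]) for lab in labels]
    if got != expected:
        raise AssertionError(f"length rule mismatch: {got} != {expected}")
    return out


def concat_features(
    window: np.ndarray, cfg: WaveletConfig | None = None, fs: float = 256.0
) -> WaveletFeatures:
    """Decompose every channel and concatenate into the model's 1D vector.

    Channel-major order: channel 0's ``[A_L, D_L, ..., D_1]`` block, then
    channel 1's, and so on.  ``band_map`` covers each concat index exactly
    once.
    """
    cfg = cfg or WaveletConfig()
    window = np.atleast_2d(np.asarray(window, dtype=np.float64))
    labels = cfg.band_labels()
    ranges = cfg.band_ranges(fs)

    per_channel: list[dict[str, np.ndarray]] = []
    pieces: list[np.ndarray] = []
    band_map: list[tuple[int, str, tuple[float, float]]] = []
    for ch in range(window.shape[0]):
        bands = dwt_decompose(window[ch], cfg)
        per_channel.append(bands)
        for lab, rng in zip(labels, ranges):
            pieces.append(bands[lab])
            band_map.extend([(ch, lab, rng)] * len(bands[lab]))
    concat = np.concatenate(pieces)
    assert len(band_map) == len(concat)
    return WaveletFeatures(per_channel=per_channel, concat=concat, band_map=band_map)


# ------------------------------------------------------- baseline features

def time_domain_features(window: np.ndarray) -> np.ndarray:
    """Per-channel mean, population SD and RMS, flattened channel-major.

    These obey RMS^2 = mean^2 + SD^2 exactly (population convention).
    """
    w = np.atleast_2d(np.asarray(window, dtype=np.float64))
    if not np.all(np.isfinite(w)):
        raise ValueError("window contains non-finite values")
    mean = w.mean(axis=1)
    sd = w.std(axis=1)
    rms = np.sqrt((w**2).mean(axis=1))
    return np.stack([mean, sd, rms], axis=1).ravel()


def freq_domain_features(
    window: np.ndarray, fs: float, nperseg: int | None = None
) -> np.ndarray:
    """Per-channel Welch-PSD mean and median frequency, channel-major.

    Mean frequency is the spectral centroid sum(f P) / sum(P); median
    frequency splits cumulative power at 50%.
    """
    w = np.atleast_2d(np.asarray(window, dtype=np.float64))
    n = w.shape[1]
    if nperseg is None:
        nperseg = min(256, n)
    if n < nperseg or n < 8:
        raise ValueError(f"window length {n} too short for Welch (nperseg={nperseg})")
    freqs, psd = sps.welch(w, fs=fs, nperseg=nperseg, axis=1)
    total = psd.sum(axis=1)
    total = np.where(total == 0, 1.0, total)
    mean_f = (psd * freqs).sum(axis=1) / total
    cum = np.cumsum(psd, axis=1) / total[:, None]
    idx = np.argmax(cum >= 0.5, axis=1)
    median_f = freqs[idx]
    return np.stack([mean_f, median_f], axis=1).ravel()
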