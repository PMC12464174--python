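"""Surrogate EEG generator with controllable spectral structure.

Two signal regimes are emulated.  *Background* activity is pink (1/f) noise
plus an alpha-band oscillation, the dominant structure of resting scalp EEG.
*Seizure-like* activity adds a periodic ~3 Hz spike-and-wave discharge (the
classic generalized-seizure morphology: a sharp spike riding on a slow wave)
and an elevated gamma-band sinusoid.  The two regimes therefore differ in the
low-frequency (delta--alpha) and gamma bands, the bands a level-3 dyadic
wavelet decomposition separates into its A3 and D2 sub-bands at 256 Hz.

No physiological realism is claimed: waveforms are closed-form components
plus noise, chosen so that class separability is controllable and every
downstream stage (I/O, features, training, evaluation) is testable without
any dataset download.

Reproducibility: one master seed; record ``i`` draws from
``np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(i,)))`` so
each record is individually reproducible regardless of generation order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .records import EEGRecord, WindowedDataset

__all__ = [
    "BackgroundParams",
    "SeizureParams",
    "SyntheticSpec",
    "generate_record",
    "generate_dataset",
    "BONN_PRESET",
    "CHBMIT_PRESET",
    "TUSZ_PRESET",
    "preset",
]

CLASS_NAMES = ["background", "seizure"]


@dataclass(frozen=True)
class BackgroundParams:
    """Background regime: pink noise + alpha oscillation.

    ``pink_exponent`` is the spectral slope of the 1/f^a noise floor;
    ``alpha_hz``/``alpha_amp`` place a sinusoid in the alpha band.
    Amplitudes are in the same arbitrary microvolt-scale units as the noise.
    """

    pink_exponent: float = 1.0
    pink_scale: float = 1.0
    alpha_hz: float = 10.0
    alpha_amp: float = 1.0


@dataclass(frozen=True)
class SeizureParams:
    """Seizure regime additions: ~3 Hz spike-wave bursts + gamma power.

    ``spike_rate_hz`` is the repetition rate of the spike-and-wave complex,
    ``burst_amp`` its amplitude, ``gamma_hz``/``gamma_amp`` the added
    gamma-band sinusoid (kept below fs/4 at 256 Hz so it lands in the D2
    sub-band of a 3-level decomposition).
    """

    spike_rate_hz: float = 3.0
    burst_amp: float = 2.0
    gamma_hz: float = 40.0
    gamma_amp: float = 0.5


@dataclass(frozen=True)
class SyntheticSpec:
    """Full description of a synthetic dataset draw."""

    n_records: int = 100
    n_channels: int = 1
    n_samples: int = 256
    fs: float = 256.0
    seizure_fraction: float = 0.5
    background_params: BackgroundParams = field(default_factory=BackgroundParams)
    seizure_params: SeizureParams = field(default_factory=SeizureParams)
    noise_sd: float = 0.5
    phase_jitter_sd: float = 0.1
    seed: int = 0

    def validate(self) -> None:
        if self.n_records <= 0 or self.n_channels <= 0:
            raise ValueError("n_records and n_channels must be positive")
        if self.n_samples < 8:
            raise ValueError(f"n_samples must be >= 8, got {self.n_samples}")
        if self.fs <= 0:
            raise ValueError(f"fs must be positive, got {self.fs}")
        if not 0.0 <= self.seizure_fraction <= 1.0:
            raise ValueError(f"seizure_fraction outside [0, 1]: {self.seizure_fraction}")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


# Dataset-shaped presets: single-channel Bonn-style segments, long multi-channel
# CHB-MIT-style records, and one-second 22-channel TUSZ-style windows.
BONN_PRESET = SyntheticSpec(n_channels=1, n_samples=4097, fs=173.61)
CHBMIT_PRESET = SyntheticSpec(n_channels=22, n_samples=2560, fs=256.0)
TUSZ_PRESET = SyntheticSpec(n_channels=22, n_samples=256, fs=256.0)

_PRESETS = {"bonn": BONN_PRESET, "chbmit": CHBMIT_PRESET, "tusz": TUSZ_PRESET}


def preset(name: str, **overrides) -> SyntheticSpec:
    """Return a named preset (``bonn``, ``chbmit`` or ``tusz``), optionally
    overriding any :class:`SyntheticSpec` field."""
    try:
        base = _PRESETS[name]
    except KeyError:
        raise ValueError(f"unknown preset {name!r}; choose from {sorted(_PRESETS)}")
    if not overrides:
        return base
    from dataclasses import replace

    return replace(base, **overrides)


def _pink_noise(rng: np.random.Generator, n: int, exponent: float, scale: float) -> np.ndarray:
    """1/f^a noise by spectral shaping of white Gaussian noise."""
    white = rng.standard_normal(n)
    if scale == 0.0:
        return np.zeros(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=1.0)
    with np.errstate(divide="ignore"):
        shaping = np.where(freqs > 0, freqs ** (-exponent / 2.0), 0.0)
    x = np.fft.irfft(spec * shaping, n=n)
    sd = x.std()
    if sd > 0:
        x *= scale / sd
    return x


def _spike_wave(t: np.ndarray, rate_hz: float, amp: float, phase: float) -> np.ndarray:
    """Periodic spike-and-wave complex: a slow sawtooth wave with a sharp
    Gaussian spike at the start of each cycle."""
    cycle = t * rate_hz + phase / (2 * np.pi)
    frac = cycle - np.floor(cycle)
    wave = sps.sawtooth(2 * np.pi * cycle, width=0.5)
    spike = np.exp(-0.5 * ((frac - 0.1) / 0.02) ** 2)
    return amp * (0.5 * wave + spike)


def _record_rng(seed: int, index: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(index,)))


def generate_record(
    spec: SyntheticSpec, label: str = "background", seed: int | None = None, index: int = 0
) -> EEGRecord:
    """Draw one ``n_channels x n_samples`` record in the given regime.

    ``label`` is ``"background"`` or ``"seizure"``.  The oscillatory
    components share a phase across channels (with small per-channel jitter);
    the pink and white noise are independent per channel.  ``seed`` defaults
    to ``spec.seed``; ``index`` is the counter used to derive the per-record
    stream, so the same (seed, index) pair always yields the same record.
    """
    spec.validate()
    if label not in CLASS_NAMES:
        raise ValueError(f"label must be one of {CLASS_NAMES}, got {label!r}")
    rng = _record_rng(spec.seed if seed is None else seed, index)
    bg, sz = spec.background_params, spec.seizure_params
    t = np.arange(spec.n_samples) / spec.fs
    base_phase = rng.uniform(0, 2 * np.pi)

    data = np.empty((spec.n_channels, spec.n_samples))
    for ch in range(spec.n_channels):
        phase = base_phase + rng.normal(0.0, spec.phase_jitter_sd)
        x = _pink_noise(rng, spec.n_samples, bg.pink_exponent, bg.pink_scale)
        x = x + bg.alpha_amp * np.sin(2 * np.pi * bg.alpha_hz * t + phase)
        if label == "seizure":
            x = x + _spike_wave(t, sz.spike_rate_hz, sz.burst_amp, phase)
            x = x + sz.gamma_amp * np.sin(2 * np.pi * sz.gamma_hz * t + phase)
        if spec.noise_sd > 0:
            x = x + rng.normal(0.0, spec.noise_sd, spec.n_samples)
        data[ch] = x

    return EEGRecord(
        data=data,
        fs=spec.fs,
        record_id=f"synth-{label}-{index:04d}",
    )


def generate_dataset(spec: SyntheticSpec) -> WindowedDataset:
    """Draw a labelled dataset of ``spec.n_records`` single-window records.

    Exactly ``round(seizure_fraction * n_records)`` records are seizure
    class; seizure records occupy the leading indices (shuffle downstream —
    training is responsible for its own shuffling).  Ordering and content are
    fully determined by ``spec.seed``.
    """
    spec.validate()
    n_seiz = int(round(spec.seizure_fraction * spec.n_records))
    labels = np.zeros(spec.n_records, dtype=np.int64)
    labels[:n_seiz] = 1

    windows = np.empty((spec.n_records, spec.n_channels, spec.n_samples))
    provenance: list[tuple[str, int]] = []
    for i, lab in enumerate(labels):
        rec = generate_record(spec, CLASS_NAMES[int(lab)], index=i)
        windows[i] = rec.data
        provenance.append((rec.record_id, 0))

    return WindowedDataset(
        windows=windows,
        labels=labels,  # seizure=1, background=0
        class_names=list(CLASS_NAMES),
        provenance=provenance,
    )
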