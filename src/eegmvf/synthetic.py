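"""Synthetic 3-channel motor-imagery EEG with a controllable class signal.

The generator emulates the statistical structure the classification
pipeline relies on: cue-locked 4 s epochs at 250 Hz over C3 / Cz / C4, a
1/f (pink) background, and sensorimotor oscillations in the mu (8-13 Hz)
and beta (13-30 Hz) bands whose amplitude is attenuated contralaterally to
the imagined hand (event-related desynchronization, ERD).  Left-hand
imagery attenuates C4, right-hand imagery attenuates C3; Cz is unaffected.

Two additional, optional class cues exist for controlled experiments:

``broadband_gain_delta``
    multiplies the whole trial of one class by ``1 + delta``.  Note that a
    trial-wide multiplicative gain is removed exactly by any per-channel
    z-scoring downstream, so this cue is only informative for pipelines
    that keep absolute amplitude.
``highband_amp``
    adds a 70 Hz oscillation (outside the 4-40 Hz analysis band) to every
    channel of one class.  This cue survives z-scoring (it changes the
    waveform, not just its scale) but is erased by the 4-40 Hz bandpass
    feeding the time-frequency view, making it a raw-view-only signal for
    fusion ablations.

No attempt is made at physiological realism beyond this (no artifacts, no
volume conduction).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, replace

import numpy as np
from scipy import signal as sps

__all__ = [
    "CHANNELS",
    "LABELS",
    "SynthParams",
    "SyntheticDataset",
    "generate_trial",
    "generate_dataset",
    "band_power",
]

CHANNELS = ("C3", "Cz", "C4")
LABELS = ("left", "right")

#: amplitude of the mu / beta oscillation before ERD scaling (arbitrary units,
#: beta set weaker than mu as in sensorimotor recordings)
_MU_AMP = 1.0
_BETA_AMP = 0.5
_HIGHBAND_FREQ = 70.0  # Hz, above the 4-40 Hz analysis band


@dataclass(frozen=True)
class SynthParams:
    """Generator configuration; defaults are the package's study conditions."""

    fs: float = 250.0
    n_channels: int = 3
    epoch_s: float = 4.0
    mu_band: tuple[float, float] = (8.0, 13.0)
    beta_band: tuple[float, float] = (13.0, 30.0)
    erd_depth: float = 0.5
    noise_level: float = 1.0
    broadband_gain_delta: float = 0.0
    highband_amp: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.erd_depth <= 1.0:
            raise ValueError(f"erd_depth must be in [0, 1], got {self.erd_depth}")
        n = self.fs * self.epoch_s
        if abs(n - round(n)) > 1e-9:
            raise ValueError("fs * epoch_s must be an integer number of samples")
        nyq = self.fs / 2.0
        for name, (lo, hi) in (("mu_band", self.mu_band), ("beta_band", self.beta_band)):
            if not 0.0 < lo < hi < nyq:
                raise ValueError(f"{name} must lie inside (0, fs/2)")
        if self.n_channels != 3:
            raise ValueError("the generator models exactly 3 channels (C3, Cz, C4)")

    @property
    def n_samples(self) -> int:
        return int(round(self.fs * self.epoch_s))


@dataclass
class SyntheticDataset:
    """Balanced collection of labelled synthetic trials."""

    trials: np.ndarray  # (n_trials, 3, n_samples)
    labels: list[str]
    params: SynthParams = field(repr=False)

    def __len__(self) -> int:
        return len(self.labels)

    def to_dict(self) -> dict:
        return {
            "trials": self.trials,
            "labels": np.asarray(self.labels),
            "params": asdict(self.params),
        }


def _pink_noise(rng: np.random.Generator, n: int) -> np.ndarray:
    """1/f-amplitude noise via spectral shaping of white noise (unit RMS)."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n)
    shaping = np.empty_like(f)
    shaping[0] = 0.0  # kill DC
    shaping[1:] = 1.0 / np.sqrt(f[1:])
    x = np.fft.irfft(spec * shaping, n)
    return x / np.std(x)


def _oscillation(
    rng: np.random.Generator, band: tuple[float, float], amp: float, t: np.ndarray
) -> np.ndarray:
    """Sinusoid at a random in-band frequency with uniform random phase."""
    f = rng.uniform(*band)
    phase = rng.uniform(0.0, 2.0 * np.pi)
    return amp * np.sin(2.0 * np.pi * f * t + phase)


def generate_trial(
    label: str, params: SynthParams, trial_seed: int
) -> np.ndarray:
    """One labelled 3 x (fs * epoch_s) cue-locked MI epoch.

    Per channel: pink noise + mu-band and beta-band oscillations with random
    phases.  The channel contralateral to the imagined hand has its
    oscillation amplitudes scaled by ``1 - erd_depth``.
    """
    if label not in LABELS:
        raise ValueError(f"label must be one of {LABELS}, got {label!r}")
    rng = np.random.default_rng(
        np.random.SeedSequence(entropy=int(trial_seed), spawn_key=(0,))
    )
    n = params.n_samples
    t = np.arange(n) / params.fs
    # ERD convention: left-hand MI attenuates the contralateral (right
    # hemisphere) electrode C4; right-hand MI attenuates C3.
    attenuated_channel = "C4" if label == "left" else "C3"
    data = np.empty((3, n), dtype=np.float64)
    for c, ch_name in enumerate(CHANNELS):
        osc = _oscillation(rng, params.mu_band, _MU_AMP, t) + _oscillation(
            rng, params.beta_band, _BETA_AMP, t
        )
        scale = (1.0 - params.erd_depth) if ch_name == attenuated_channel else 1.0
        osc_rms = np.sqrt(0.5 * _MU_AMP**2 + 0.5 * _BETA_AMP**2)
        noise = params.noise_level * osc_rms * _pink_noise(rng, n)
        data[c] = scale * osc + noise
        if params.highband_amp and label == "left":
            phase = rng.uniform(0.0, 2.0 * np.pi)
            data[c] += params.highband_amp * np.sin(
                2.0 * np.pi * _HIGHBAND_FREQ * t + phase
            )
    if params.broadband_gain_delta and label == "left":
        data *= 1.0 + params.broadband_gain_delta
    return data


def generate_dataset(n_per_class: int, params: SynthParams) -> SyntheticDataset:
    """Balanced dataset of ``2 * n_per_class`` trials.

    Per-trial seeds are spawned deterministically from ``params.seed`` so the
    whole dataset regenerates bit-identically.
    """
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    ss = np.random.SeedSequence(params.seed)
    trial_seeds = ss.generate_state(2 * n_per_class, dtype=np.uint32)
    trials = []
    labels = []
    for i in range(2 * n_per_class):
        label = LABELS[i % 2]  # interleaved left/right
        trials.append(generate_trial(label, params, int(trial_seeds[i])))
        labels.append(label)
    return SyntheticDataset(np.stack(trials), labels, params)


def band_power(x: np.ndarray, band: tuple[float, float], fs: float) -> float:
    """Integrated Welch-periodogram power of ``x`` within ``band`` (Hz)."""
    low, high = band
    if not 0.0 < low < high < fs / 2.0:
        raise ValueError(f"band must satisfy 0 < low < high < fs/2, got {band}")
    x = np.asarray(x, dtype=np.float64)
    nperseg = min(len(x), 256)
    freqs, psd = sps.welch(x, fs=fs, nperseg=nperseg)
    mask = (freqs >= low) & (freqs <= high)
    if mask.sum() < 2:
        return float(psd[mask].sum() * (freqs[1] - freqs[0]))
    return float(np.trapezoid(psd[mask], freqs[mask]))


def with_params(params: SynthParams, **changes) -> SynthParams:
    """Convenience: a copy of ``params`` with fields replaced."""
    return replace(params, **changes)
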