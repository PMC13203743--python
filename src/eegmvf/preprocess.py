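"""Bandpass filtering, fixed-length slicing, and raw-view normalisation.

Pipeline order is fixed: filter -> epoch -> slice.  When a continuous
recording is available the filter is applied to it before epoching so that
filter edge transients fall outside the epochs; for trials that exist only
as epochs (e.g. synthetic data) the filter runs on the epoch itself.
"""

from __future__ import annotations

import numpy as np
from scipy import signal as sps

__all__ = [
    "bandpass_filter",
    "slice_trial",
    "reassemble_slices",
    "normalize_raw",
]

#: samples per slice at 250 Hz and the default 0.5 s slice length
DEFAULT_SLICE_S = 0.5


def bandpass_filter(
    data: np.ndarray, fs: float, low: float = 4.0, high: float = 40.0, order: int = 4
) -> np.ndarray:
    """Zero-phase Butterworth band-pass, applied per channel.

    The filter is a 4th-order Butterworth run forward-backward
    (``sosfiltfilt``), so the passband gain is the squared magnitude
    response and the phase response is exactly zero.
    """
    if not 0.0 < low < high < fs / 2.0:
        raise ValueError(f"invalid band ({low}, {high}) for fs={fs}")
    data = np.asarray(data, dtype=np.float64)
    sos = sps.butter(order, [low, high], btype="bandpass", fs=fs, output="sos")
    return sps.sosfiltfilt(sos, data, axis=-1)


def slice_trial(trial: np.ndarray, fs: float = 250.0, slice_s: float = DEFAULT_SLICE_S) -> np.ndarray:
    """Partition a (C, L) trial into contiguous non-overlapping slices.

    Returns an (n, C, T) array with T = fs * slice_s; a 4 s trial at 250 Hz
    yields n = 8 slices of 125 samples.  L must be divisible by T: slicing
    is an exact partition, never padded.
    """
    trial = np.asarray(trial)
    if trial.ndim != 2:
        raise ValueError(f"trial must be 2-D (channels, samples), got {trial.shape}")
    t_f = fs * slice_s
    if abs(t_f - round(t_f)) > 1e-9:
        raise ValueError(f"fs * slice_s must be an integer, got {t_f}")
    t = int(round(t_f))
    n_ch, length = trial.shape
    if length % t:
        raise ValueError(f"trial length {length} not divisible by slice length {t}")
    n = length // t
    return trial.reshape(n_ch, n, t).transpose(1, 0, 2).copy()


def reassemble_slices(slices: np.ndarray) -> np.ndarray:
    """Inverse of :func:`slice_trial`: (n, C, T) -> (C, n*T)."""
    slices = np.asarray(slices)
    n, n_ch, t = slices.shape
    return slices.transpose(1, 0, 2).reshape(n_ch, n * t)


def normalize_raw(slice_: np.ndarray, eps: float = 1e-12) -> np.ndarray:
    """Per-channel z-score of one (C, T) slice (zero mean, unit variance).

    A constant channel maps to all zeros (the epsilon guard prevents a
    division by zero).  The z-score is exactly scale-invariant, so any
    multiplicative amplitude information is removed here by design.
    """
    slice_ = np.asarray(slice_, dtype=np.float64)
    mean = slice_.mean(axis=-1, keepdims=True)
    std = slice_.std(axis=-1, keepdims=True)
    # a channel whose spread is at floating-point noise level relative to
    # its magnitude is constant: map it to exact zeros
    constant = std <= eps * np.maximum(1.0, np.abs(mean))
    out = (slice_ - mean) / np.where(constant, 1.0, std)
    return np.where(constant, 0.0, out)
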