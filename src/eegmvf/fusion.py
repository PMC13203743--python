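"""Multi-view fusion: raw-signal dimension alignment and 1x1-conv gating.

The time-frequency branch produces (3, T, F) tensors; the z-scored raw
slice is only (3, T).  The raw view is replicated along the frequency
axis (outer product with an all-ones F-vector) so both views share a
shape, then each view passes through its own 1x1 convolution (3 -> 3
channels, with bias) and the results are added element-wise.  The two
convolutions act as learned per-channel gates over the views.

Initialisation: both gates start at the identity by default, so each
view contributes from the first step and either can be amplified or
suppressed by training.  A "gated" scheme (identity time-frequency gate,
near-zero raw gate) is available as a config axis but recruits the raw
view much more slowly.  With the raw branch frozen at zero the layer
reduces exactly to the single-view time-frequency pipeline.
"""

from __future__ import annotations

import numpy as np

from . import nn

__all__ = ["align_raw", "fuse", "FusionGate", "VIEWS"]

VIEWS = ("fused", "tfr_only", "raw_only")


def align_raw(raw_slice: np.ndarray, n_freqs: int = 125) -> np.ndarray:
    """Replicate a (3, T) slice along frequency: out[c, t, f] = raw[c, t].

    Accepts a single slice or any leading batch shape (..., 3, T); output
    gains a trailing axis of length ``n_freqs``.
    """
    raw_slice = np.asarray(raw_slice)
    if raw_slice.shape[-2] != 3:
        raise ValueError(f"expected channel axis of size 3, got {raw_slice.shape}")
    ones = np.ones(n_freqs, dtype=raw_slice.dtype)
    return raw_slice[..., None] * ones


def fuse(
    tfr_tensor: np.ndarray,
    raw_aligned: np.ndarray,
    w_tfr: np.ndarray,
    b_tfr: np.ndarray,
    w_raw: np.ndarray,
    b_raw: np.ndarray,
) -> np.ndarray:
    """Pure-numpy reference of the fusion layer (eval semantics).

    ``w_*`` are (3, 3) matrices (output channel x input channel), ``b_*``
    length-3 biases.  Inputs are (3, T, F) or batched (B, 3, T, F);
    output = w_tfr . tfr + b_tfr + w_raw . raw + b_raw per pixel.
    """
    tfr_tensor = np.asarray(tfr_tensor)
    raw_aligned = np.asarray(raw_aligned)
    if tfr_tensor.shape != raw_aligned.shape:
        raise ValueError(
            f"view shapes differ: {tfr_tensor.shape} vs {raw_aligned.shape}"
        )
    out = np.einsum("oc,...cij->...oij", w_tfr, tfr_tensor)
    out += np.einsum("oc,...cij->...oij", w_raw, raw_aligned)
    bias = (np.asarray(b_tfr) + np.asarray(b_raw)).reshape(3, 1, 1)
    return out + bias


class FusionGate(nn.Module):
    """Trainable two-view 1x1-conv fusion layer.

    ``view`` selects the ablation variant: ``fused`` trains both gates,
    ``tfr_only`` freezes the raw gate at zero, ``raw_only`` freezes the
    time-frequency gate at zero (and initialises the raw gate at the
    identity instead).
    """

    def __init__(
        self,
        rng: np.random.Generator,
        view: str = "fused",
        init: str = "identity",
        raw_init_scale: float = 0.1,
    ):
        super().__init__()
        if view not in VIEWS:
            raise ValueError(f"view must be one of {VIEWS}, got {view!r}")
        self.view = view
        eye = np.eye(3, dtype=np.float32).reshape(3, 3, 1, 1)
        if init == "identity":
            w_tfr = eye.copy()
            w_raw = eye.copy()
        elif init == "gated":
            w_tfr = eye.copy()
            w_raw = rng.normal(0.0, raw_init_scale, (3, 3, 1, 1)).astype(np.float32)
        elif init == "random":
            w_tfr = rng.normal(0.0, 0.5, (3, 3, 1, 1)).astype(np.float32)
            w_raw = rng.normal(0.0, 0.5, (3, 3, 1, 1)).astype(np.float32)
        else:
            raise ValueError(f"unknown init scheme {init!r}")
        if view == "raw_only":
            w_raw = eye.copy()
        self.w_tfr = nn.Parameter(w_tfr)
        self.b_tfr = nn.Parameter(np.zeros(3, dtype=np.float32))
        self.w_raw = nn.Parameter(w_raw)
        self.b_raw = nn.Parameter(np.zeros(3, dtype=np.float32))
        if view == "tfr_only":
            self._freeze("w_raw", "b_raw")
        elif view == "raw_only":
            self._freeze("w_tfr", "b_tfr")

    def _freeze(self, *names: str) -> None:
        for name in names:
            p: nn.Parameter = getattr(self, name)
            p.data = np.zeros_like(p.data) if name.startswith("w") else p.data
            p.requires_grad = False
        if "w_raw" in names:
            self.w_raw.data[:] = 0.0
        if "w_tfr" in names:
            self.w_tfr.data[:] = 0.0

    def forward(self, tfr_view: nn.Tensor, raw_view: nn.Tensor) -> nn.Tensor:
        if tfr_view.shape != raw_view.shape:
            raise ValueError(
                f"view shapes differ: {tfr_view.shape} vs {raw_view.shape}"
            )
        if self.view == "tfr_only":
            return nn.conv2d(tfr_view, self.w_tfr, self.b_tfr)
        if self.view == "raw_only":
            return nn.conv2d(raw_view, self.w_raw, self.b_raw)
        out = nn.conv2d(tfr_view, self.w_tfr, self.b_tfr)
        return out + nn.conv2d(raw_view, self.w_raw, self.b_raw)
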