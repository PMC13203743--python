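"""Per-slice CNN encoding, Transformer temporal modelling, classification.

Architecture, in the order a trial flows through it:

1. every fused slice tensor (3 x T x F) is encoded by a lightweight CNN
   backbone ending in global average pooling -> a d-vector per slice;
2. the n slice embeddings form a feature matrix M (d x n, columns in
   temporal order) that a standard Transformer encoder contextualises
   with scaled dot-product self-attention (scaling 1 / sqrt(d_k));
3. the classification head mean-pools the n tokens and applies a single
   linear layer + softmax over the two classes (left / right hand).

Backbones are compact trainable networks built on the package's own
autodiff runtime.  ``shuffle_micro`` is a reduced-depth ShuffleNet-style
network (pointwise group convolutions, channel shuffle, depthwise 3x3,
stride-2 units with average-pool shortcut concatenation); ``cnn_micro``
is a plain strided-convolution baseline used for backbone-swap
ablations.  Global average pooling makes both size-agnostic, so the
125 x 125 maps are fed at native resolution.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .fusion import FusionGate

__all__ = [
    "ConfigError",
    "BackboneConfig",
    "AttentionConfig",
    "build_backbone",
    "ShuffleMicro",
    "CNNMicro",
    "TransformerEncoder",
    "ClassifierHead",
    "MVFNet",
    "encode_slice",
    "encode_sequence",
    "classify",
    "cross_entropy_loss",
    "sinusoidal_positions",
]


class ConfigError(ValueError):
    """Invalid architecture / attention configuration."""


# ---------------------------------------------------------------------------
# configs
# ---------------------------------------------------------------------------


@dataclass
class BackboneConfig:
    """Slice-encoder selection.

    ``pretrained`` loads a previously saved backbone state from
    ``weights_path`` (transfer learning from another training run); no
    weights ship with the package.
    """

    architecture: str = "shuffle_micro"
    pretrained: bool = False
    weights_path: str | None = None

    @property
    def feature_dim(self) -> int:
        dims = {"shuffle_micro": 48, "cnn_micro": 48}
        try:
            return dims[self.architecture]
        except KeyError:
            raise ConfigError(f"unknown backbone {self.architecture!r}") from None


@dataclass
class AttentionConfig:
    """Transformer-encoder hyperparameters (model_dim must match d)."""

    n_layers: int = 2
    n_heads: int = 4
    model_dim: int = 48
    ff_dim: int = 192
    dropout: float = 0.1
    positional_encoding: str = "sinusoidal"  # sinusoidal | learned | none

    def __post_init__(self):
        if self.model_dim % self.n_heads:
            raise ConfigError("model_dim must be divisible by n_heads")
        if self.positional_encoding not in ("sinusoidal", "learned", "none"):
            raise ConfigError(
                f"unknown positional encoding {self.positional_encoding!r}"
            )

    @property
    def d_k(self) -> int:
        return self.model_dim // self.n_heads


# ---------------------------------------------------------------------------
# backbones
# ---------------------------------------------------------------------------


def channel_shuffle(x: nn.Tensor, groups: int) -> nn.Tensor:
    """ShuffleNet channel shuffle: interleave channels across groups."""
    b, c, h, w = x.shape
    return (
        x.reshape(b, groups, c // groups, h, w)
        .transpose(0, 2, 1, 3, 4)
        .reshape(b, c, h, w)
    )


class _ConvBNReLU(nn.Module):
    def __init__(self, rng, cin, cout, k, stride=1, padding=0, groups=1, relu=True):
        super().__init__()
        self.conv = nn.Conv2d(
            cin, cout, k, rng, stride=stride, padding=padding, groups=groups, bias=False
        )
        self.bn = nn.BatchNorm2d(cout)
        self.relu = relu

    def forward(self, x):
        x = self.bn(self.conv(x))
        return x.relu() if self.relu else x


class ShuffleUnit(nn.Module):
    """ShuffleNet v1 unit: gconv 1x1 -> shuffle -> dw 3x3 -> gconv 1x1.

    stride 1: residual addition (cin == cout); stride 2: 3x3/2 average-pool
    shortcut concatenated with the branch (branch emits cout - cin).
    """

    def __init__(self, rng, cin, cout, stride, groups=3):
        super().__init__()
        self.stride = stride
        branch_out = cout - cin if stride == 2 else cout
        mid = cout // 4
        if mid % groups or cin % groups or branch_out % groups:
            raise ConfigError("shuffle unit channels must divide the group count")
        self.groups = groups
        self.reduce = _ConvBNReLU(rng, cin, mid, 1, groups=groups)
        self.dw = _ConvBNReLU(
            rng, mid, mid, 3, stride=stride, padding=1, groups=mid, relu=False
        )
        self.expand = _ConvBNReLU(rng, mid, branch_out, 1, groups=groups, relu=False)

    def forward(self, x):
        branch = self.expand(self.dw(channel_shuffle(self.reduce(x), self.groups)))
        if self.stride == 2:
            shortcut = nn.avg_pool2d(x, 3, stride=2, padding=1)
            return nn.concat([shortcut, branch], axis=1).relu()
        return (x + branch).relu()


class ShuffleMicro(nn.Module):
    """Reduced-depth ShuffleNet-style backbone, d = 48.

    A 2x2 average pool in front of the stem halves the spatial size of
    the smooth 125 x 125 scalograms before any convolution; the CNN
    proper then runs at 62 x 62.
    """

    def __init__(self, rng: np.random.Generator):
        super().__init__()
        self.stem = _ConvBNReLU(rng, 3, 12, 3, stride=2, padding=1)
        self.stages = [
            ShuffleUnit(rng, 12, 24, stride=2),
            ShuffleUnit(rng, 24, 24, stride=1),
            ShuffleUnit(rng, 24, 48, stride=2),
            ShuffleUnit(rng, 48, 48, stride=1),
        ]
        self.feature_dim = 48

    def forward(self, x):
        x = self.stem(nn.avg_pool2d(x, 2))
        for unit in self.stages:
            x = unit(x)
        return nn.global_avg_pool(x)


class CNNMicro(nn.Module):
    """Plain strided-conv backbone (ablation baseline), d = 48."""

    def __init__(self, rng: np.random.Generator):
        super().__init__()
        self.blocks = [
            _ConvBNReLU(rng, 3, 16, 3, stride=2, padding=1),
            _ConvBNReLU(rng, 16, 32, 3, stride=2, padding=1),
            _ConvBNReLU(rng, 32, 48, 3, stride=2, padding=1),
        ]
        self.feature_dim = 48

    def forward(self, x):
        x = nn.avg_pool2d(x, 2)
        for blk in self.blocks:
            x = blk(x)
        return nn.global_avg_pool(x)


_BACKBONES = {"shuffle_micro": ShuffleMicro, "cnn_micro": CNNMicro}


def build_backbone(cfg: BackboneConfig, rng: np.random.Generator) -> nn.Module:
    if cfg.architecture not in _BACKBONES:
        raise ConfigError(f"unknown backbone {cfg.architecture!r}")
    backbone = _BACKBONES[cfg.architecture](rng)
    if cfg.pretrained:
        if not cfg.weights_path:
            raise ConfigError("pretrained=True requires weights_path")
        state = dict(np.load(cfg.weights_path))
        backbone.load_state(state)
    return backbone


# ---------------------------------------------------------------------------
# transformer encoder
# ---------------------------------------------------------------------------


def sinusoidal_positions(n: int, d: int) -> np.ndarray:
    """Standard sin/cos positional-encoding table, shape (n, d)."""
    pos = np.arange(n)[:, None]
    i = np.arange(d // 2)[None, :]
    angles = pos / (10000.0 ** (2 * i / d))
    pe = np.zeros((n, d), dtype=np.float32)
    pe[:, 0::2] = np.sin(angles)
    pe[:, 1::2] = np.cos(angles)
    return pe


class MultiHeadAttention(nn.Module):
    def __init__(self, cfg: AttentionConfig, rng: np.random.Generator):
        super().__init__()
        d = cfg.model_dim
        self.h, self.d_k = cfg.n_heads, cfg.d_k
        self.wq = nn.Linear(d, d, rng)
        self.wk = nn.Linear(d, d, rng)
        self.wv = nn.Linear(d, d, rng)
        self.wo = nn.Linear(d, d, rng)
        self.last_attention: np.ndarray | None = None

    def forward(self, x: nn.Tensor) -> nn.Tensor:
        b, n, d = x.shape

        def split(t):  # (B, n, d) -> (B, h, n, d_k)
            return t.reshape(b, n, self.h, self.d_k).transpose(0, 2, 1, 3)

        q, k, v = split(self.wq(x)), split(self.wk(x)), split(self.wv(x))
        scores = (q @ k.swapaxes(-1, -2)) * (1.0 / np.sqrt(self.d_k))
        attn = nn.softmax(scores, axis=-1)  # rows sum to 1
        self.last_attention = attn.data
        ctx = (attn @ v).transpose(0, 2, 1, 3).reshape(b, n, d)
        return self.wo(ctx)


class EncoderLayer(nn.Module):
    """Post-norm Transformer encoder layer (attention + position-wise FF)."""

    def __init__(self, cfg: AttentionConfig, rng: np.random.Generator):
        super().__init__()
        self.attn = MultiHeadAttention(cfg, rng)
        self.ff1 = nn.Linear(cfg.model_dim, cfg.ff_dim, rng)
        self.ff2 = nn.Linear(cfg.ff_dim, cfg.model_dim, rng)
        self.ln1 = nn.LayerNorm(cfg.model_dim)
        self.ln2 = nn.LayerNorm(cfg.model_dim)
        self.drop = nn.Dropout(cfg.dropout, rng)

    def forward(self, x):
        x = self.ln1(x + self.drop(self.attn(x)))
        return self.ln2(x + self.drop(self.ff2(self.ff1(x).relu())))


class TransformerEncoder(nn.Module):
    def __init__(self, cfg: AttentionConfig, rng: np.random.Generator, max_len: int = 64):
        super().__init__()
        self.cfg = cfg
        if cfg.positional_encoding == "learned":
            self.pos = nn.Parameter(
                0.02 * rng.standard_normal((max_len, cfg.model_dim)).astype(np.float32)
            )
        else:
            self.pos = None
        self.layers = [EncoderLayer(cfg, rng) for _ in range(cfg.n_layers)]

    def forward(self, x: nn.Tensor) -> nn.Tensor:
        b, n, d = x.shape
        if self.cfg.positional_encoding == "sinusoidal":
            x = x + nn.Tensor(sinusoidal_positions(n, d)[None])
        elif self.cfg.positional_encoding == "learned":
            x = x + self.pos[:n].reshape(1, n, d)
        for layer in self.layers:
            x = layer(x)
        return x


class ClassifierHead(nn.Module):
    """Temporal mean-pool over tokens -> linear -> (softmax at predict time)."""

    def __init__(self, d: int, rng: np.random.Generator, n_classes: int = 2):
        super().__init__()
        self.fc = nn.Linear(d, n_classes, rng)

    def forward(self, tokens: nn.Tensor) -> nn.Tensor:
        return self.fc(tokens.mean(axis=1))


# ---------------------------------------------------------------------------
# full network
# ---------------------------------------------------------------------------


class MVFNet(nn.Module):
    """Fusion gate + per-slice backbone + Transformer + classifier.

    ``forward`` consumes numpy batches: the time-frequency view
    (B, n, 3, T, F) and the z-scored raw view (B, n, 3, T); it returns
    class logits (B, 2).  The raw view is aligned to (3, T, F) on the fly.
    The stored ``tfr_mean`` / ``tfr_std`` standardise the time-frequency
    maps with statistics estimated once on the training set.
    """

    def __init__(
        self,
        rng: np.random.Generator,
        backbone_cfg: BackboneConfig | None = None,
        attn_cfg: AttentionConfig | None = None,
        view: str = "fused",
        use_transformer: bool = True,
        fusion_init: str = "identity",
    ):
        super().__init__()
        self.backbone_cfg = backbone_cfg or BackboneConfig()
        self.fusion = FusionGate(rng, view=view, init=fusion_init)
        self.backbone = build_backbone(self.backbone_cfg, rng)
        d = self.backbone.feature_dim
        self.attn_cfg = attn_cfg or AttentionConfig(model_dim=d, ff_dim=4 * d)
        if self.attn_cfg.model_dim != d:
            raise ConfigError(
                f"attention model_dim {self.attn_cfg.model_dim} != backbone d {d}"
            )
        self.use_transformer = use_transformer
        self.encoder = TransformerEncoder(self.attn_cfg, rng)
        self.head = ClassifierHead(d, rng)
        self.tfr_mean = np.zeros(1, dtype=np.float32)
        self.tfr_std = np.ones(1, dtype=np.float32)

    # -- statistics -------------------------------------------------------
    def set_tfr_scale(self, maps: np.ndarray) -> None:
        """Estimate dataset-level standardisation from training maps."""
        self.tfr_mean = np.asarray([maps.mean()], dtype=np.float32)
        self.tfr_std = np.asarray([max(maps.std(), 1e-12)], dtype=np.float32)

    # -- forward ----------------------------------------------------------
    def forward(self, tfr_batch: np.ndarray, raw_batch: np.ndarray) -> nn.Tensor:
        b, n, c, t, f = tfr_batch.shape
        tfr = (tfr_batch.astype(np.float32) - self.tfr_mean[0]) / self.tfr_std[0]
        raw_aligned = np.broadcast_to(
            raw_batch.astype(np.float32)[..., None], (b, n, c, t, f)
        )
        tfr_t = nn.Tensor(tfr.reshape(b * n, c, t, f))
        raw_t = nn.Tensor(np.ascontiguousarray(raw_aligned.reshape(b * n, c, t, f)))
        fused = self.fusion(tfr_t, raw_t)
        m = self.backbone(fused)  # (B*n, d)
        tokens = m.reshape(b, n, -1)
        if self.use_transformer:
            tokens = self.encoder(tokens)
        return self.head(tokens)

    def predict_proba(self, tfr_batch: np.ndarray, raw_batch: np.ndarray) -> np.ndarray:
        self.eval()
        with nn.no_grad():
            logits = self.forward(tfr_batch, raw_batch)
            return nn.softmax(logits, axis=-1).data

    @property
    def feature_dim(self) -> int:
        return self.backbone.feature_dim


# ---------------------------------------------------------------------------
# functional surface (single-sample convenience wrappers)
# ---------------------------------------------------------------------------


def encode_slice(fused: np.ndarray, backbone: nn.Module) -> np.ndarray:
    """Encode one (3, T, F) fused tensor into a d-vector (eval mode)."""
    backbone.eval()
    with nn.no_grad():
        out = backbone(nn.Tensor(np.asarray(fused, dtype=np.float32)[None]))
    return out.data[0]


def encode_sequence(m: np.ndarray, encoder: TransformerEncoder) -> np.ndarray:
    """Contextualise a (d, n) feature matrix; returns (d, n)."""
    d, n = m.shape
    if d != encoder.cfg.model_dim:
        raise ConfigError(f"feature dim {d} != model_dim {encoder.cfg.model_dim}")
    encoder.eval()
    with nn.no_grad():
        out = encoder(nn.Tensor(np.asarray(m.T, dtype=np.float32)[None]))
    return out.data[0].T


def classify(context: np.ndarray, head: ClassifierHead) -> np.ndarray:
    """Probability pair (left, right) from a (d, n) contextual matrix."""
    head.eval()
    with nn.no_grad():
        logits = head(nn.Tensor(np.asarray(context.T, dtype=np.float32)[None]))
        return nn.softmax(logits, axis=-1).data[0]


def cross_entropy_loss(pred: np.ndarray, labels: np.ndarray) -> float:
    """Mean negative log-likelihood of integer labels under probability pairs.

    ``pred`` is (N, 2) of probabilities (rows on the simplex), ``labels``
    integer class indices.  L = -(1/N) * sum_i log pred[i, y_i].
    """
    pred = np.asarray(pred, dtype=np.float64)
    labels = np.asarray(labels)
    if pred.ndim != 2 or len(labels) != len(pred):
        raise ValueError("pred must be (N, C) with one label per row")
    if labels.min() < 0 or labels.max() >= pred.shape[1]:
        raise ValueError("label outside class range")
    p = np.clip(pred[np.arange(len(pred)), labels], 1e-300, None)
    return float(-np.mean(np.log(p)))
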