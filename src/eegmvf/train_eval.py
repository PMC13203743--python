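"""Per-subject training, accuracy evaluation, and the ablation harness.

Training recipe: Adam, initial learning rate 0.002, batch size 32, 50
epochs, cross-entropy loss, end-to-end over fusion gates + backbone +
Transformer + head; the last-epoch model is evaluated (no schedule, no
weight decay, no early stopping).  One prediction per trial: the 8-slice
sequence is a single sample.

Features are precomputed once per dataset (bandpass -> slice -> CWT maps
for the time-frequency view; slice -> z-score for the raw view) and
cached in a :class:`FeatureSet`, so ablation grids re-use them across
configurations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict, replace

import numpy as np

from . import nn
from .dataio import EpochedTrial
from .model import AttentionConfig, BackboneConfig, MVFNet
from .preprocess import bandpass_filter, normalize_raw, slice_trial
from .synthetic import LABELS, SyntheticDataset
from .tfr import CWTConfig, build_sequence

__all__ = [
    "TrainConfig",
    "EvalResult",
    "FeatureSet",
    "prepare_features",
    "split_features",
    "train_subject",
    "evaluate",
    "accuracy",
    "run_ablation",
    "save_model",
    "load_model",
]

logger = logging.getLogger(__name__)

_LABEL_TO_INT = {lab: i for i, lab in enumerate(LABELS)}


@dataclass
class TrainConfig:
    """Training hyperparameters and ablation switches."""

    optimizer: str = "adam"
    lr: float = 0.002
    batch_size: int = 32
    epochs: int = 50
    seed: int = 0
    view: str = "fused"  # fused | tfr_only | raw_only
    pretrained: bool = False
    weights_path: str | None = None
    backbone: str = "shuffle_micro"
    use_transformer: bool = True
    raw_norm: str = "slice"  # z-score per slice ("slice") or per trial ("trial")
    band: tuple[float, float] = (4.0, 40.0)
    eval_epoch: str = "last"  # last | best (best = lowest training loss)

    def __post_init__(self):
        if self.lr <= 0:
            raise ValueError("lr must be positive")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.optimizer != "adam":
            raise ValueError("only the adam optimizer is supported")


@dataclass
class EvalResult:
    """Per-subject accuracies (%) with their mean and sample std."""

    per_subject: dict[str, float]
    config: dict = field(default_factory=dict)

    @property
    def mean(self) -> float:
        return float(np.mean(list(self.per_subject.values())))

    @property
    def std(self) -> float:
        vals = list(self.per_subject.values())
        return float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0

    def row(self) -> dict:
        out = dict(self.per_subject)
        out["mean"] = self.mean
        out["std"] = self.std
        return out


@dataclass
class FeatureSet:
    """Precomputed model inputs for a set of trials."""

    tfr: np.ndarray  # (N, n, 3, T, F) float32 magnitude maps
    raw: np.ndarray  # (N, n, 3, T) float32 z-scored raw slices
    labels: np.ndarray  # (N,) int, 0 = left, 1 = right
    indices: np.ndarray  # provenance indices into the source dataset

    def __len__(self) -> int:
        return len(self.labels)


def _as_trial_arrays(data) -> tuple[np.ndarray, np.ndarray, float]:
    """Normalise input to (trials (N, 3, L), labels (N,), fs)."""
    if isinstance(data, FeatureSet):
        raise TypeError("already a FeatureSet")
    if isinstance(data, SyntheticDataset):
        labels = np.asarray([_LABEL_TO_INT[lab] for lab in data.labels])
        return data.trials, labels, data.params.fs
    if isinstance(data, (list, tuple)) and data and isinstance(data[0], EpochedTrial):
        trials = np.stack([t.data for t in data])
        labels = np.asarray([_LABEL_TO_INT[t.label] for t in data])
        return trials, labels, data[0].fs
    raise TypeError(f"unsupported dataset type {type(data)!r}")


def prepare_features(
    data,
    cwt_cfg: CWTConfig | None = None,
    cfg: TrainConfig | None = None,
) -> FeatureSet:
    """Bandpass/slice/CWT the TFR view and slice/z-score the raw view.

    The time-frequency branch sees the band-passed signal; the raw branch
    sees the as-recorded signal (no filtering), z-scored per channel and
    per slice (or per trial with ``raw_norm='trial'``).
    """
    if isinstance(data, FeatureSet):
        return data
    cwt_cfg = cwt_cfg or CWTConfig()
    cfg = cfg or TrainConfig()
    trials, labels, fs = _as_trial_arrays(data)
    tfr_list, raw_list = [], []
    for trial in trials:
        filtered = bandpass_filter(trial, fs, *cfg.band)
        tfr_list.append(
            build_sequence(slice_trial(filtered, fs), cwt_cfg).astype(np.float32)
        )
        raw_slices = slice_trial(trial, fs)
        if cfg.raw_norm == "trial":
            centred = normalize_raw(trial)
            raw_slices = slice_trial(centred, fs)
        else:
            raw_slices = np.stack([normalize_raw(s) for s in raw_slices])
        raw_list.append(raw_slices.astype(np.float32))
    return FeatureSet(
        tfr=np.stack(tfr_list),
        raw=np.stack(raw_list),
        labels=labels,
        indices=np.arange(len(labels)),
    )


def split_features(
    features: FeatureSet, test_fraction: float, seed: int
) -> tuple[FeatureSet, FeatureSet]:
    """Stratified train/test split; asserts the index sets are disjoint."""
    rng = np.random.default_rng(seed)
    test_idx: list[int] = []
    for cls in np.unique(features.labels):
        cls_idx = np.flatnonzero(features.labels == cls)
        n_test = int(round(test_fraction * len(cls_idx)))
        test_idx.extend(rng.permutation(cls_idx)[:n_test])
    test_mask = np.zeros(len(features), dtype=bool)
    test_mask[test_idx] = True

    def take(mask):
        return FeatureSet(
            tfr=features.tfr[mask],
            raw=features.raw[mask],
            labels=features.labels[mask],
            indices=features.indices[mask],
        )

    train, test = take(~test_mask), take(test_mask)
    assert not set(train.indices) & set(test.indices), "train/test overlap"
    return train, test


def _build_model(cfg: TrainConfig, rng: np.random.Generator) -> MVFNet:
    backbone_cfg = BackboneConfig(
        architecture=cfg.backbone,
        pretrained=cfg.pretrained,
        weights_path=cfg.weights_path,
    )
    d = backbone_cfg.feature_dim
    return MVFNet(
        rng,
        backbone_cfg=backbone_cfg,
        attn_cfg=AttentionConfig(model_dim=d, ff_dim=4 * d),
        view=cfg.view,
        use_transformer=cfg.use_transformer,
    )


def train_subject(
    train_data, cfg: TrainConfig, cwt_cfg: CWTConfig | None = None
) -> tuple[MVFNet, list[float]]:
    """End-to-end training on one subject's trials.

    Returns the trained model and the per-epoch mean training loss.  All
    randomness (parameter init, batch order, dropout) derives from
    ``cfg.seed``, so identical calls produce identical models on CPU.
    """
    features = prepare_features(train_data, cwt_cfg, cfg)
    classes, counts = np.unique(features.labels, return_counts=True)
    if len(classes) < 2:
        raise ValueError("training set must contain both classes")
    rng = np.random.default_rng(cfg.seed)
    model = _build_model(cfg, rng)
    model.set_tfr_scale(features.tfr)
    opt = nn.Adam(model.parameters(), lr=cfg.lr)
    n = len(features)
    history: list[float] = []
    best = (np.inf, None)
    for epoch in range(cfg.epochs):
        model.train()
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            logits = model(features.tfr[idx], features.raw[idx])
            loss = nn.cross_entropy(logits, features.labels[idx])
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(loss.item() * len(idx))
        epoch_loss = float(np.sum(losses) / n)
        history.append(epoch_loss)
        logger.info("epoch %d/%d loss %.4f", epoch + 1, cfg.epochs, epoch_loss)
        if cfg.eval_epoch == "best" and epoch_loss < best[0]:
            best = (epoch_loss, {k: v.copy() for k, v in model.named_state().items()})
    if cfg.eval_epoch == "best" and best[1] is not None:
        model.load_state(best[1])
    model.eval()
    return model, history


def predict(model: MVFNet, features: FeatureSet, batch_size: int = 32) -> np.ndarray:
    """Per-trial argmax predictions (ints)."""
    preds = []
    for start in range(0, len(features), batch_size):
        sl = slice(start, start + batch_size)
        proba = model.predict_proba(features.tfr[sl], features.raw[sl])
        preds.append(np.argmax(proba, axis=1))
    return np.concatenate(preds)


def accuracy(pred: np.ndarray, labels: np.ndarray) -> float:
    """correct / total * 100."""
    pred, labels = np.asarray(pred), np.asarray(labels)
    if len(pred) != len(labels) or len(pred) == 0:
        raise ValueError("prediction / label length mismatch or empty")
    return float(np.mean(pred == labels) * 100.0)


def evaluate(model: MVFNet, test_data, cwt_cfg: CWTConfig | None = None) -> float:
    """Accuracy (%) of per-trial argmax predictions on labelled test trials."""
    features = prepare_features(test_data, cwt_cfg)
    if len(features) == 0:
        raise ValueError("empty test set")
    return accuracy(predict(model, features), features.labels)


def run_ablation(
    datasets: dict[str, tuple],
    grid: list[TrainConfig],
    cwt_cfg: CWTConfig | None = None,
):
    """Train/evaluate every config on every subject; one table row per config.

    ``datasets`` maps subject id -> (train, test) where each element is a
    FeatureSet or a raw dataset accepted by :func:`prepare_features`.
    Failed runs are recorded as NaN with the error logged, never dropped
    silently.  Returns a pandas DataFrame with per-subject columns plus
    ``mean`` and ``std`` (sample std over subjects).
    """
    import pandas as pd

    if not grid:
        raise ValueError("ablation grid is empty")
    rows = []
    for cfg in grid:
        per_subject: dict[str, float] = {}
        for subject, (train_data, test_data) in datasets.items():
            try:
                model, _ = train_subject(train_data, cfg, cwt_cfg)
                per_subject[subject] = evaluate(model, test_data, cwt_cfg)
            except Exception:
                logger.exception(
                    "ablation run failed (subject=%s, view=%s)", subject, cfg.view
                )
                per_subject[subject] = float("nan")
        result = EvalResult(per_subject, config=asdict(cfg))
        row = {
            "view": cfg.view,
            "backbone": cfg.backbone,
            "pretrained": cfg.pretrained,
            "transformer": cfg.use_transformer,
        }
        row.update(result.row())
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# canned experiments (scaled-down study conditions on synthetic data)
# ---------------------------------------------------------------------------


def _derived_seeds(seed: int, n: int) -> list[int]:
    """n deterministic sub-seeds (< 2**31) from one master seed."""
    return [int(s) for s in np.random.SeedSequence(seed).generate_state(n) >> 1]


def erd_separability_experiment(
    seed: int = 0,
    erd_depth: float = 0.9,
    n_train_per_class: int = 100,
    n_test_per_class: int = 50,
    epochs: int = 10,
    view: str = "fused",
) -> dict:
    """Train on lateralised-ERD synthetic data and evaluate held out.

    The defaults are the package's training-sanity study conditions:
    erd_depth 0.9, 100 trials/class, 10 epochs, random initialisation.
    Returns train/test accuracy (%) and the loss history.
    """
    from .synthetic import SynthParams, generate_dataset

    s_train, s_test, s_model = _derived_seeds(seed, 3)
    train = generate_dataset(
        n_train_per_class, SynthParams(erd_depth=erd_depth, seed=s_train)
    )
    test = generate_dataset(
        n_test_per_class, SynthParams(erd_depth=erd_depth, seed=s_test)
    )
    cfg = TrainConfig(epochs=epochs, seed=s_model, view=view)
    ftrain, ftest = prepare_features(train, cfg=cfg), prepare_features(test, cfg=cfg)
    model, history = train_subject(ftrain, cfg)
    return {
        "model": model,
        "history": history,
        "train_accuracy": accuracy(predict(model, ftrain), ftrain.labels),
        "test_accuracy": accuracy(predict(model, ftest), ftest.labels),
        "n_test": 2 * n_test_per_class,
    }


def fusion_ablation_experiment(
    seed: int = 0,
    n_seeds: int = 3,
    n_per_class: int = 40,
    epochs: int = 40,
    highband_amp: float = 1.0,
):
    """Three-view ablation on data whose only class cue is raw-view-only.

    The generator adds a supra-band (70 Hz) class-dependent oscillation;
    the 4-40 Hz bandpass erases it from the time-frequency view while the
    z-scored raw view keeps the waveform cue.  Runs fused / tfr_only /
    raw_only over ``n_seeds`` independent datasets and returns the
    accuracy table plus the median margins over the time-frequency-only
    view.
    """
    from .synthetic import SynthParams, generate_dataset

    sub = _derived_seeds(seed, 2 * n_seeds + 1)
    datasets = {}
    for k in range(n_seeds):
        params_train = SynthParams(
            erd_depth=0.0, highband_amp=highband_amp, seed=sub[2 * k]
        )
        params_test = SynthParams(
            erd_depth=0.0, highband_amp=highband_amp, seed=sub[2 * k + 1]
        )
        datasets[f"seed{k}"] = (
            prepare_features(generate_dataset(n_per_class, params_train)),
            prepare_features(generate_dataset(n_per_class, params_test)),
        )
    base = TrainConfig(epochs=epochs, seed=sub[-1])
    grid = [replace(base, view=v) for v in ("fused", "tfr_only", "raw_only")]
    table = run_ablation(datasets, grid)
    cols = [c for c in table.columns if c.startswith("seed")]
    accs = {row["view"]: np.asarray([row[c] for c in cols]) for _, row in table.iterrows()}
    margins = {
        "fused_vs_tfr_only": float(np.median(accs["fused"] - accs["tfr_only"])),
        "raw_only_vs_tfr_only": float(np.median(accs["raw_only"] - accs["tfr_only"])),
    }
    return table, margins


# ---------------------------------------------------------------------------
# checkpoints
# ---------------------------------------------------------------------------


def save_model(model: MVFNet, cfg: TrainConfig, path) -> None:
    """Serialise weights + config to an .npz checkpoint."""
    import json

    state = model.named_state()
    state["__config__"] = np.frombuffer(
        json.dumps(asdict(cfg)).encode(), dtype=np.uint8
    )
    np.savez(path, **state)


def load_model(path) -> tuple[MVFNet, TrainConfig]:
    """Rebuild a model from an .npz checkpoint."""
    import json

    blob = dict(np.load(path))
    cfg_dict = json.loads(bytes(blob.pop("__config__").tobytes()).decode())
    cfg_dict["band"] = tuple(cfg_dict["band"])
    cfg = TrainConfig(**cfg_dict)
    model = _build_model(cfg, np.random.default_rng(cfg.seed))
    model.load_state(blob)
    model.eval()
    return model, cfg


def with_config(cfg: TrainConfig, **changes) -> TrainConfig:
    """Copy of ``cfg`` with fields replaced (ablation-grid helper)."""
    return replace(cfg, **changes)
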