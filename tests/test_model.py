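"""Backbone encoding, attention mechanics, classification head, loss."""

import numpy as np
import pytest

from eegmvf import (
    AttentionConfig,
    BackboneConfig,
    ConfigError,
    MVFNet,
    TransformerEncoder,
    build_backbone,
    classify,
    cross_entropy_loss,
    encode_sequence,
    encode_slice,
)
from eegmvf import nn
from eegmvf.model import ClassifierHead, MultiHeadAttention, sinusoidal_positions


@pytest.fixture(scope="module")
def backbone():
    return build_backbone(BackboneConfig(), np.random.default_rng(0))


class TestBackbone:
    def test_embedding_length_is_feature_dim(self, backbone):
        rng = np.random.default_rng(1)
        for _ in range(2):
            vec = encode_slice(rng.normal(size=(3, 125, 125)), backbone)
            assert vec.shape == (BackboneConfig().feature_dim,)

    def test_eval_mode_deterministic(self, backbone):
        x = np.random.default_rng(2).normal(size=(3, 125, 125))
        assert np.array_equal(encode_slice(x, backbone), encode_slice(x, backbone))

    def test_unknown_architecture_rejected(self):
        with pytest.raises(ConfigError):
            build_backbone(
                BackboneConfig(architecture="resnet152"), np.random.default_rng(0)
            )

    def test_pretrained_roundtrip_from_checkpoint(self, tmp_path, backbone):
        # "pretrained" consumes a previously saved backbone state
        path = tmp_path / "weights.npz"
        np.savez(path, **backbone.named_state())
        loaded = build_backbone(
            BackboneConfig(pretrained=True, weights_path=str(path)),
            np.random.default_rng(99),
        )
        x = np.random.default_rng(3).normal(size=(3, 125, 125))
        assert np.allclose(encode_slice(x, loaded), encode_slice(x, backbone))

    def test_pretrained_without_path_rejected(self):
        with pytest.raises(ConfigError):
            build_backbone(BackboneConfig(pretrained=True), np.random.default_rng(0))


class TestAttention:
    def test_rows_are_stochastic(self):
        cfg = AttentionConfig(model_dim=8, n_heads=2, ff_dim=16)
        mha = MultiHeadAttention(cfg, np.random.default_rng(0))
        x = nn.Tensor(np.random.default_rng(1).normal(size=(2, 5, 8)).astype(np.float32))
        mha(x)
        sums = mha.last_attention.sum(axis=-1)
        assert np.allclose(sums, 1.0, atol=1e-6)

    def test_single_token_attention_is_one(self):
        cfg = AttentionConfig(model_dim=8, n_heads=4, ff_dim=16)
        mha = MultiHeadAttention(cfg, np.random.default_rng(0))
        x = nn.Tensor(np.random.default_rng(1).normal(size=(3, 1, 8)).astype(np.float32))
        mha(x)
        assert np.array_equal(mha.last_attention, np.ones((3, 4, 1, 1), dtype=np.float32))

    def test_matches_hand_coded_attention_oracle(self):
        # single layer, single head, fixed tiny weights, 2-token sequence
        cfg = AttentionConfig(n_layers=1, n_heads=1, model_dim=4, ff_dim=8)
        mha = MultiHeadAttention(cfg, np.random.default_rng(0))
        rng = np.random.default_rng(5)
        for lin in (mha.wq, mha.wk, mha.wv, mha.wo):
            lin.weight.data = rng.normal(0, 0.5, (4, 4)).astype(np.float32)
            lin.bias.data = rng.normal(0, 0.1, 4).astype(np.float32)
        x = rng.normal(size=(1, 2, 4)).astype(np.float32)
        out = mha(nn.Tensor(x)).data[0]

        q = x[0] @ mha.wq.weight.data + mha.wq.bias.data
        k = x[0] @ mha.wk.weight.data + mha.wk.bias.data
        v = x[0] @ mha.wv.weight.data + mha.wv.bias.data
        scores = q @ k.T / np.sqrt(4.0)
        attn = np.exp(scores) / np.exp(scores).sum(axis=-1, keepdims=True)
        ref = (attn @ v) @ mha.wo.weight.data + mha.wo.bias.data
        rel = np.abs(out - ref).max() / np.abs(ref).max()
        assert rel <= 1e-6

    def test_model_dim_must_divide_heads(self):
        with pytest.raises(ConfigError):
            AttentionConfig(model_dim=10, n_heads=4)

    def test_encode_sequence_shape_and_dim_check(self):
        cfg = AttentionConfig(model_dim=8, n_heads=2, ff_dim=16, dropout=0.0)
        enc = TransformerEncoder(cfg, np.random.default_rng(0))
        m = np.random.default_rng(1).normal(size=(8, 6))  # d x n
        out = encode_sequence(m, enc)
        assert out.shape == (8, 6)
        with pytest.raises(ConfigError):
            encode_sequence(np.zeros((5, 6)), enc)

    def test_no_positions_makes_pooled_output_permutation_invariant(self):
        cfg = AttentionConfig(
            model_dim=8, n_heads=2, ff_dim=16, dropout=0.0, positional_encoding="none"
        )
        enc = TransformerEncoder(cfg, np.random.default_rng(0))
        m = np.random.default_rng(2).normal(size=(8, 6))
        pooled = encode_sequence(m, enc).mean(axis=1)
        perm = np.random.default_rng(3).permutation(6)
        pooled_perm = encode_sequence(m[:, perm], enc).mean(axis=1)
        assert np.allclose(pooled, pooled_perm, atol=1e-5)

    def test_sinusoidal_positions_break_permutation_invariance(self):
        cfg = AttentionConfig(model_dim=8, n_heads=2, ff_dim=16, dropout=0.0)
        enc = TransformerEncoder(cfg, np.random.default_rng(0))
        m = np.random.default_rng(2).normal(size=(8, 6))
        pooled = encode_sequence(m, enc).mean(axis=1)
        pooled_rev = encode_sequence(m[:, ::-1], enc).mean(axis=1)
        assert not np.allclose(pooled, pooled_rev, atol=1e-4)

    def test_sinusoidal_table_values(self):
        pe = sinusoidal_positions(4, 6)
        assert pe[0, 0] == 0.0 and pe[0, 1] == 1.0
        assert pe[2, 0] == pytest.approx(np.sin(2.0), abs=1e-6)


class TestClassifier:
    def test_probabilities_sum_to_one(self):
        head = ClassifierHead(8, np.random.default_rng(0))
        probs = classify(np.random.default_rng(1).normal(size=(8, 6)), head)
        assert probs.shape == (2,)
        assert np.isclose(probs.sum(), 1.0, atol=1e-6)

    def test_zero_weights_give_uniform(self):
        head = ClassifierHead(8, np.random.default_rng(0))
        head.fc.weight.data[:] = 0.0
        head.fc.bias.data[:] = 0.0
        probs = classify(np.random.default_rng(1).normal(size=(8, 6)), head)
        assert np.allclose(probs, 0.5, atol=1e-7)

    def test_deterministic_in_eval(self):
        head = ClassifierHead(8, np.random.default_rng(0))
        ctx = np.random.default_rng(2).normal(size=(8, 6))
        assert np.array_equal(classify(ctx, head), classify(ctx, head))


class TestCrossEntropy:
    def test_perfect_predictions_give_zero(self):
        pred = np.array([[1.0, 0.0], [0.0, 1.0]])
        assert cross_entropy_loss(pred, np.array([0, 1])) == pytest.approx(0.0, abs=1e-9)

    def test_uniform_predictions_give_ln2(self):
        pred = np.full((4, 2), 0.5)
        assert cross_entropy_loss(pred, np.array([0, 1, 0, 1])) == pytest.approx(
            np.log(2.0), abs=1e-9
        )

    def test_matches_per_sample_oracle(self):
        rng = np.random.default_rng(3)
        logits = rng.normal(size=(8, 2))
        pred = np.exp(logits) / np.exp(logits).sum(axis=1, keepdims=True)
        labels = rng.integers(0, 2, 8)
        ref = sum(-np.log(pred[i, labels[i]]) for i in range(8)) / 8
        assert cross_entropy_loss(pred, labels) == pytest.approx(ref, abs=1e-10)

    def test_invalid_labels_rejected(self):
        with pytest.raises(ValueError):
            cross_entropy_loss(np.full((2, 2), 0.5), np.array([0, 3]))


class TestEndToEndShapes:
    def test_trial_to_probability_shape_law(self):
        # trial -> n x 3 x 125 x 125 maps + n x 3 x 125 raw -> d x n -> simplex
        rng = np.random.default_rng(0)
        model = MVFNet(rng)
        tfr = rng.random((2, 8, 3, 125, 125)).astype(np.float32)
        raw = rng.normal(size=(2, 8, 3, 125)).astype(np.float32)
        probs = model.predict_proba(tfr, raw)
        assert probs.shape == (2, 2)
        assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-6)

    def test_attention_dim_mismatch_rejected(self):
        with pytest.raises(ConfigError):
            MVFNet(
                np.random.default_rng(0),
                attn_cfg=AttentionConfig(model_dim=32, ff_dim=128),
            )
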