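"""Training loop contracts, evaluation arithmetic, ablation table structure."""

import numpy as np
import pytest

from eegmvf import (
    FeatureSet,
    SynthParams,
    TrainConfig,
    accuracy,
    evaluate,
    generate_dataset,
    prepare_features,
    run_ablation,
    split_features,
    train_subject,
)
from eegmvf.train_eval import EvalResult, load_model, predict, save_model, with_config


def tiny_cfg(**kw):
    defaults = dict(epochs=2, seed=0, batch_size=4)
    defaults.update(kw)
    return TrainConfig(**defaults)


@pytest.fixture(scope="module")
def tiny_features():
    ds = generate_dataset(2, SynthParams(erd_depth=0.9, noise_level=0.3, seed=9))
    return prepare_features(ds)


class TestPrepareFeatures:
    def test_shapes(self, small_features):
        n = len(small_features)
        assert small_features.tfr.shape == (n, 8, 3, 125, 125)
        assert small_features.raw.shape == (n, 8, 3, 125)
        assert small_features.labels.shape == (n,)

    def test_raw_view_is_z_scored_per_slice(self, small_features):
        raw = small_features.raw.astype(np.float64)
        assert np.allclose(raw.mean(axis=-1), 0.0, atol=1e-4)
        assert np.allclose(raw.std(axis=-1), 1.0, atol=1e-3)

    def test_tfr_view_nonnegative(self, small_features):
        assert np.all(small_features.tfr >= 0)


class TestTrainSubject:
    def test_smoke_two_trials_two_epochs(self, tiny_features):
        model, history = train_subject(tiny_features, tiny_cfg())
        assert len(history) == 2
        assert all(np.isfinite(h) for h in history)

    def test_single_class_rejected(self, tiny_features):
        mask = tiny_features.labels == 0
        one_class = FeatureSet(
            tfr=tiny_features.tfr[mask],
            raw=tiny_features.raw[mask],
            labels=tiny_features.labels[mask],
            indices=tiny_features.indices[mask],
        )
        with pytest.raises(ValueError):
            train_subject(one_class, tiny_cfg())

    def test_identical_seed_gives_identical_final_loss(self, tiny_features):
        _, h1 = train_subject(tiny_features, tiny_cfg())
        _, h2 = train_subject(tiny_features, tiny_cfg())
        assert h1 == h2

    def test_invalid_hyperparameters_rejected(self):
        with pytest.raises(ValueError):
            TrainConfig(lr=0.0)
        with pytest.raises(ValueError):
            TrainConfig(epochs=0)

    def test_loss_decreases_on_separable_data(self, erd_run):
        history = erd_run["history"]
        assert history[-1] < history[0]

    def test_high_training_accuracy_on_separable_data(self, erd_run):
        # erd_depth 0.9, reduced recipe (10 epochs, random init)
        assert erd_run["train_accuracy"] >= 95.0


class TestEvaluate:
    def test_accuracy_matches_hand_count(self):
        pred = np.array([0, 1, 1, 0, 1])
        labels = np.array([0, 1, 0, 0, 0])
        assert accuracy(pred, labels) == pytest.approx(60.0)

    def test_perfect_model_scores_100(self, tiny_features):
        assert accuracy(tiny_features.labels, tiny_features.labels) == 100.0

    def test_empty_test_set_rejected(self):
        with pytest.raises(ValueError):
            accuracy(np.array([]), np.array([]))

    def test_untrained_model_near_chance_on_balanced_data(self):
        # a freshly initialised model knows nothing: expected 50% within
        # the 95% binomial interval over 200 balanced trials
        from eegmvf.model import MVFNet

        ds = generate_dataset(100, SynthParams(erd_depth=0.5, seed=13))
        feats = prepare_features(ds)
        model = MVFNet(np.random.default_rng(0))
        model.set_tfr_scale(feats.tfr)
        acc = accuracy(predict(model, feats), feats.labels)
        assert 43.0 <= acc <= 57.0  # 50 +/- 1.96 * sqrt(.25/200) * 100


class TestSplitAndResult:
    def test_split_is_disjoint_and_stratified(self, small_features):
        train, test = split_features(small_features, 0.25, seed=0)
        assert len(train) + len(test) == len(small_features)
        assert not set(train.indices) & set(test.indices)
        assert np.bincount(test.labels).tolist() == [2, 2]  # 25% of 10 per class

    def test_eval_result_mean_std_recompute(self):
        # formula check: mean +/- std over per-subject entries (sample std)
        per = {
            "S1": 71.17, "S2": 64.05, "S3": 82.30, "S4": 95.89, "S5": 90.78,
            "S6": 80.76, "S7": 83.57, "S8": 92.93, "S9": 78.66,
        }
        res = EvalResult(per)
        vals = np.array(list(per.values()))
        assert res.mean == pytest.approx(vals.mean(), abs=1e-9)
        assert res.std == pytest.approx(vals.std(ddof=1), abs=1e-9)
        assert res.mean == pytest.approx(82.23, abs=0.005)
        assert res.std == pytest.approx(10.27, abs=0.005)


class TestAblationHarness:
    def test_three_view_grid_yields_three_rows(self, tiny_features):
        train, test = split_features(tiny_features, 0.5, seed=0)
        grid = [tiny_cfg(view=v) for v in ("fused", "tfr_only", "raw_only")]
        table = run_ablation({"synthA": (train, test)}, grid)
        assert len(table) == 3
        assert set(table["view"]) == {"fused", "tfr_only", "raw_only"}
        assert {"synthA", "mean", "std"} <= set(table.columns)

    def test_transformer_grid_shares_subject_columns(self, tiny_features):
        train, test = split_features(tiny_features, 0.5, seed=0)
        grid = [tiny_cfg(use_transformer=True), tiny_cfg(use_transformer=False)]
        table = run_ablation({"synthA": (train, test)}, grid)
        assert len(table) == 2
        assert table["synthA"].notna().all()

    def test_empty_grid_rejected(self, tiny_features):
        with pytest.raises(ValueError):
            run_ablation({"s": (tiny_features, tiny_features)}, [])


class TestCheckpoint:
    def test_save_load_roundtrip_preserves_predictions(self, tmp_path, tiny_features):
        cfg = tiny_cfg()
        model, _ = train_subject(tiny_features, cfg)
        before = predict(model, tiny_features)
        path = tmp_path / "model.npz"
        save_model(model, cfg, path)
        loaded, cfg2 = load_model(path)
        assert cfg2 == cfg
        assert np.array_equal(predict(loaded, tiny_features), before)

    def test_with_config_replaces_fields(self):
        cfg = with_config(TrainConfig(), view="raw_only", epochs=7)
        assert cfg.view == "raw_only" and cfg.epochs == 7
        assert TrainConfig().view == "fused"
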