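import numpy as np
import pytest

from alarmsieve.errors import ValidationError
from alarmsieve.model import ModelConfig
from alarmsieve.synthetic_data import SyntheticSpec, generate_dataset
from alarmsieve.train_eval import (
    ConfusionCounts,
    TrainConfig,
    challenge_score,
    confusion_from_labels,
    cross_validate,
    predict,
    tpr_tnr_acc,
    train,
)

TINY_MODEL = ModelConfig(kernel_sizes=(5, 10), filters=4, alarm_dim=8, rule_dim=8)


def tiny_train_config(**over):
    base = dict(max_epochs=5, batch_size=32, learning_rate=0.003, dropout=0.0,
                rng_seed=0)
    base.update(over)
    return TrainConfig(**base)


@pytest.fixture(scope="module")
def small_dataset():
    spec = SyntheticSpec(n_records=40, record_seconds=30, fs=125, noise_sd=0.01,
                         true_fraction=0.5, rng_seed=7)
    return [rec for rec, _ in generate_dataset(spec)[0]]


class TestMetrics:
    def test_perfect_classifier(self):
        assert challenge_score(ConfusionCounts(50, 50, 0, 0)) == 1.0
        assert tpr_tnr_acc(ConfusionCounts(50, 50, 0, 0)) == (1.0, 1.0, 1.0)

    def test_known_value(self):
        cc = ConfusionCounts(TP=96, TN=86, FP=14, FN=4)
        assert challenge_score(cc) == pytest.approx(182 / 216)

    def test_all_wrong(self):
        assert challenge_score(ConfusionCounts(0, 0, 10, 10)) == 0.0

    def test_zero_counts_rejected(self):
        with pytest.raises(ValidationError):
            challenge_score(ConfusionCounts())

    def test_rates_arithmetic(self):
        tpr, tnr, acc = tpr_tnr_acc(ConfusionCounts(9, 0, 10, 1))
        assert tpr == pytest.approx(0.9)
        assert tnr == 0.0
        assert acc == pytest.approx(9 / 20)

    def test_undefined_rate_flagged_none(self):
        tpr, tnr, acc = tpr_tnr_acc(ConfusionCounts(0, 5, 5, 0))
        assert tpr is None and tnr == 0.5

    def test_score_bounded_by_accuracy(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            tp, tn, fp, fn = (int(v) for v in rng.integers(0, 50, 4))
            if tp + tn + fp + fn == 0:
                continue
            cc = ConfusionCounts(tp, tn, fp, fn)
            _, _, acc = tpr_tnr_acc(cc)
            assert challenge_score(cc) <= acc + 1e-12
            if fn == 0:
                assert challenge_score(cc) == pytest.approx(acc)

    def test_score_decreases_with_fn(self):
        scores = [challenge_score(ConfusionCounts(10, 10, 5, fn))
                  for fn in range(5)]
        assert all(a > b for a, b in zip(scores, scores[1:]))

    def test_confusion_from_labels(self):
        cc = confusion_from_labels(
            ["true_alarm", "true_alarm", "false_alarm", "false_alarm"],
            ["true_alarm", "false_alarm", "true_alarm", "false_alarm"],
        )
        assert (cc.TP, cc.FN, cc.FP, cc.TN) == (1, 1, 1, 1)


class TestTrain:
    def test_loss_decreases_on_separable_data(self, small_dataset):
        cfg = tiny_train_config(max_epochs=12)
        _, hist = train(small_dataset, None, cfg, TINY_MODEL)
        assert hist["total"].iloc[-1] < hist["total"].iloc[0]

    def test_w_zero_total_equals_bce(self, small_dataset):
        cfg = tiny_train_config(constraint_weight=0.0, max_epochs=2)
        _, hist = train(small_dataset, None, cfg, TINY_MODEL)
        np.testing.assert_allclose(hist["total"], hist["bce"], rtol=1e-12)

    def test_same_seed_identical_history(self, small_dataset):
        cfg = tiny_train_config(max_epochs=2)
        _, h1 = train(small_dataset[:20], None, cfg, TINY_MODEL)
        _, h2 = train(small_dataset[:20], None, cfg, TINY_MODEL)
        assert h1["total"].tolist() == h2["total"].tolist()

    def test_empty_set_rejected(self):
        with pytest.raises(ValidationError):
            train([], None, tiny_train_config(), TINY_MODEL)

    def test_single_label_warns(self, small_dataset):
        only_true = [r for r in small_dataset if r.label == "true_alarm"]
        with pytest.warns(UserWarning, match="single label"):
            train(only_true, None, tiny_train_config(max_epochs=1), TINY_MODEL)

    def test_history_columns(self, small_dataset):
        cfg = tiny_train_config(max_epochs=3)
        _, hist = train(small_dataset[:10], None, cfg, TINY_MODEL)
        assert list(hist.columns) == ["epoch", "bce", "constraint", "total"]
        assert len(hist) == 3


@pytest.fixture(scope="module")
def fitted(small_dataset):
    cfg = tiny_train_config(max_epochs=6)
    model, _ = train(small_dataset, None, cfg, TINY_MODEL)
    return model


class TestPredict:
    def test_outputs_valid_probabilities(self, small_dataset, fitted):
        preds = predict(small_dataset[:8], fitted)
        assert ((preds["probability"] > 0) & (preds["probability"] < 1)).all()

    def test_threshold_tie_break_true(self, small_dataset, fitted):
        preds = predict(small_dataset[:4], fitted, threshold=0.0 + 1e-12)
        assert (preds["predicted"] == "true_alarm").all()

    def test_invariant_to_post_onset_content(self, small_dataset, fitted):
        import dataclasses
        rec = small_dataset[0]
        p1 = predict([rec], fitted)["probability"].iloc[0]
        extended = {
            role: np.concatenate([rec.channels[role],
                                  np.full(500, 1e3 if rec.available[role] else 0.0)])
            for role in rec.channels
        }
        rec2 = dataclasses.replace(rec, channels=extended)
        p2 = predict([rec2], fitted)["probability"].iloc[0]
        assert p1 == p2

    def test_constant_zero_record_valid(self, fitted):
        from conftest import make_record
        rec = make_record(n=5000, fs=125.0, seed=0)
        for role in rec.channels:
            rec.channels[role] = np.zeros(5000)
        preds = predict([rec], fitted)
        assert 0.0 < preds["probability"].iloc[0] < 1.0


class TestCrossValidate:
    def test_fold_structure_and_aggregate(self, small_dataset):
        cfg = tiny_train_config(max_epochs=2, folds=5)
        out = cross_validate(small_dataset, cfg, TINY_MODEL)
        assert len(out["folds"]) == 5
        assert out["predictions"].groupby("fold").size().tolist() == [8] * 5
        fold_scores = [m["score"] for m in out["folds"]]
        assert out["mean_score"] == pytest.approx(np.mean(fold_scores))

    def test_degenerate_one_per_fold(self):
        spec = SyntheticSpec(n_records=5, record_seconds=30, fs=125,
                             true_fraction=0.4, rng_seed=1,
                             type_mix={t: 0.2 for t in
                                       ("ASY", "EBR", "ETC", "VTA", "VFB")})
        recs = [rec for rec, _ in generate_dataset(spec)[0]]
        cfg = tiny_train_config(max_epochs=1, folds=5)
        out = cross_validate(recs, cfg, TINY_MODEL)
        for m in out["folds"]:
            assert m["score"] in (0.0, 1.0) or 0 <= m["score"] <= 1

    def test_too_few_records_rejected(self, small_dataset):
        cfg = tiny_train_config(folds=50)
        with pytest.raises(ValidationError):
            cross_validate(small_dataset, cfg, TINY_MODEL)


class TestAblation:
    def test_component_dimensioning(self):
        from alarmsieve.model import AlarmModel
        cfg = ModelConfig(components=("alarm_embedding",))
        model = AlarmModel(cfg, seed=0)
        assert model.params["W_c"].shape == (256 + 64,)
        cfg_full = ModelConfig()
        assert AlarmModel(cfg_full, seed=0).params["W_c"].shape == (256 + 128,)

    def test_grid_shares_folds(self, small_dataset):
        # matched seeds: the same records end up in the same held-out folds
        from alarmsieve.train_eval import ablate
        cfg = tiny_train_config(max_epochs=1)
        out = ablate(small_dataset, cfg, TINY_MODEL)
        assert set(out) == {"basic", "basic+constraint", "basic+rule", "full"}
        assert out["basic"]["components"] == ["alarm_embedding"]
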