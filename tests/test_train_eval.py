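import numpy as np
import pytest
from dataclasses import replace
from scipy.stats import spearmanr

from ecgfusion.model import FusionNet, FusionNetConfig
from ecgfusion.train_eval import (
    TrainConfig,
    evaluate,
    metrics_from_confusion,
    train,
)


def _separable_data(n_per_class=24, seed=0):
    """Two visually distinct classes in both channels."""
    cfg = FusionNetConfig.small(seed=seed)
    rng = np.random.default_rng(seed)
    t = np.arange(cfg.input_len) / 360.0
    segs, imgs, ys = [], [], []
    for label, (amp, bright) in enumerate([(0.5, 0.2), (2.5, 0.8)]):
        for _ in range(n_per_class):
            segs.append(amp * np.sin(2 * np.pi * 8 * t) + 0.05 * rng.standard_normal(t.size))
            imgs.append(
                np.clip(bright + 0.05 * rng.standard_normal(
                    (cfg.image_size, cfg.image_size, 3)), 0, 1)
            )
            ys.append(label)
    order = rng.permutation(len(ys))
    return (
        np.array(segs)[order],
        np.array(imgs)[order],
        np.array(ys)[order],
        cfg,
    )


class TestMetrics:
    def test_hand_computed_binary_counts(self):
        # TP=9, FN=1, FP=2, TN=8 for the positive class
        report = metrics_from_confusion(np.array([[9, 1], [2, 8]]), classes=("P", "N"))
        m = report.per_class["P"]
        assert m["Sen"] == pytest.approx(0.9)
        assert m["PPV"] == pytest.approx(9 / 11)
        assert m["Spec"] == pytest.approx(0.8)
        assert m["Acc"] == pytest.approx(0.85)
        assert m["F1"] == pytest.approx(0.8571, abs=1e-4)

    def test_perfect_predictions(self):
        cm = np.diag([10, 20, 5, 5, 3])
        report = metrics_from_confusion(cm)
        assert report.oa == 1.0
        for m in report.per_class.values():
            for key in ("PPV", "Sen", "Spec", "Acc", "F1"):
                assert m[key] == 1.0

    def test_oa_is_trace_over_total_and_f1_bounds(self, rng):
        for _ in range(25):
            cm = rng.integers(0, 40, size=(5, 5))
            report = metrics_from_confusion(cm)
            assert report.oa == pytest.approx(np.trace(cm) / cm.sum())
            for m in report.per_class.values():
                lo, hi = sorted((m["PPV"], m["Sen"]))
                assert lo - 1e-12 <= m["F1"] <= hi + 1e-12

    def test_row_sums_are_class_supports(self, rng):
        cm = rng.integers(0, 30, size=(5, 5))
        report = metrics_from_confusion(cm)
        for i, name in enumerate(report.classes):
            assert report.per_class[name]["support"] == cm[i].sum()

    def test_never_predicted_class_flagged(self):
        cm = np.array([[5, 0], [3, 0]])
        report = metrics_from_confusion(cm, classes=("A", "B"))
        assert report.per_class["B"]["PPV"] == 0.0
        assert report.undefined_ppv == ("B",)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            metrics_from_confusion(np.array([[1, -1], [0, 2]]), classes=("A", "B"))


class TestTraining:
    def test_separable_classes_learned_and_loss_trends_down(self):
        segs, imgs, ys, cfg = _separable_data()
        net = FusionNet(replace(cfg, n_classes=2, dropout=0.1))
        result = train(
            net, (segs, imgs, ys), cfg=TrainConfig(
                lr=1e-3, batch_size=16, epochs=20, seed=0
            ),
            classes=("0", "1"),
        )
        assert result.history["train_acc"][-1] > 0.95
        rho, _ = spearmanr(np.arange(len(result.history["loss"])),
                           result.history["loss"])
        assert rho < 0  # loss decreases on average over epochs

    def test_missing_class_warns(self):
        segs, imgs, ys, cfg = _separable_data(n_per_class=8)
        net = FusionNet(replace(cfg, dropout=0.0))  # 5-class head, 2 classes present
        with pytest.warns(UserWarning, match="absent"):
            train(net, (segs, imgs, ys),
                  cfg=TrainConfig(lr=1e-3, batch_size=16, epochs=1, seed=0))

    def test_validation_checkpoint_and_history(self):
        segs, imgs, ys, cfg = _separable_data(n_per_class=10)
        net = FusionNet(replace(cfg, n_classes=2, dropout=0.0))
        result = train(
            net, (segs, imgs, ys), (segs[:8], imgs[:8], ys[:8]),
            cfg=TrainConfig(lr=1e-3, batch_size=16, epochs=3, seed=1),
            classes=("0", "1"),
        )
        assert len(result.history["val_acc"]) == 3

    def test_bad_config_rejected(self):
        with pytest.raises(ValueError):
            TrainConfig(lr=0.0)
        with pytest.raises(ValueError):
            TrainConfig(optimizer="sgd")


class TestEvaluate:
    def test_report_consistent_with_predictions(self):
        segs, imgs, ys, cfg = _separable_data(n_per_class=10)
        net = FusionNet(replace(cfg, n_classes=2, dropout=0.0))
        train(net, (segs, imgs, ys),
              cfg=TrainConfig(lr=1e-3, batch_size=16, epochs=8, seed=2),
              classes=("0", "1"))
        report = evaluate(net, (segs, imgs, ys), classes=("0", "1"))
        assert report.confusion.sum() == len(ys)
        # row sums equal true class counts
        assert report.confusion[0].sum() == int((ys == 0).sum())
        assert 0.0 <= report.oa <= 1.0

    def test_empty_test_set_rejected(self):
        net = FusionNet(FusionNetConfig.small())
        with pytest.raises(ValueError, match="empty"):
            evaluate(net, (np.empty((0, 360)), np.empty((0, 48, 48, 3)),
                           np.empty(0, dtype=int)))
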