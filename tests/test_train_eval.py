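"""Training loop, early stopping, sweep harness and classification scoring."""

import numpy as np
import pytest

from ecgpipe.model import ArchitectureConfig, build_model
from ecgpipe.preprocess import SegmentDataset, split_dataset
from ecgpipe.synth import make_labeled_segments
from ecgpipe.train_eval import (
    TrainConfig,
    classification_report,
    dataset_to_arrays,
    hyperparameter_sweep,
    learning_rate_grid,
    batch_size_grid,
    train_model,
)

def _tiny_arch():
    """A deliberately small architecture so loop-behaviour tests run in seconds."""
    from ecgpipe.model import ConvLayerSpec, PoolSpec

    return ArchitectureConfig(
        input_length=60,
        conv1=ConvLayerSpec(8, 5, 3), pool1=PoolSpec(2, 2),
        conv2=ConvLayerSpec(8, 3, 1), pool2=PoolSpec(2, 2),
        conv3=ConvLayerSpec(8, 3, 1, batch_norm=False), se_reduction=4,
        pool3=PoolSpec(2, 2), lstm_units=8, dense_units=(8, 6),
    )


def _tiny_data(n_per_class=20, length=60, seed=0):
    """Trivially separable 5-class data: one bump position per class."""
    rng = np.random.default_rng(seed)
    X, y = [], []
    for cls in range(5):
        center = 8 + cls * 10
        for _ in range(n_per_class):
            x = 0.05 * rng.normal(size=length)
            x += np.exp(-0.5 * ((np.arange(length) - center) / 2.5) ** 2)
            X.append(x)
            y.append(cls)
    X = np.asarray(X)[:, :, None]
    y = np.asarray(y)
    order = rng.permutation(len(y))
    return X[order], y[order]


class TestTrainModel:
    def test_learns_separable_data(self):
        X, y = _tiny_data(30)
        model = build_model(_tiny_arch(), seed=0)
        cfg = TrainConfig(learning_rate=0.01, batch_size=25, max_epochs=30,
                          early_stop_patience=30, seed=0)
        model, history = train_model(model, (X[:100], y[:100]), (X[100:], y[100:]), cfg)
        assert max(history.val_accuracy) >= 0.95
        assert history.stopped_epoch == len(history.val_loss)

    def test_early_stopping_contract(self):
        """Stops within patience epochs of the best validation loss."""
        X, y = _tiny_data(10)
        model = build_model(_tiny_arch(), seed=1)
        cfg = TrainConfig(learning_rate=0.05, batch_size=25, max_epochs=60,
                          early_stop_patience=5, seed=1)
        model, history = train_model(model, (X[:35], y[:35]), (X[35:], y[35:]), cfg)
        best_epoch = 1 + int(np.argmin(history.val_loss))
        assert history.stopped_epoch <= best_epoch + cfg.early_stop_patience
        assert history.stopped_epoch <= cfg.max_epochs

    def test_best_weights_restored(self):
        X, y = _tiny_data(10)
        model = build_model(_tiny_arch(), seed=2)
        cfg = TrainConfig(learning_rate=0.05, batch_size=25, max_epochs=25,
                          early_stop_patience=6, seed=2)
        model, history = train_model(model, (X[:35], y[:35]), (X[35:], y[35:]), cfg)
        from ecgpipe.train_eval import _evaluate_loss_acc

        loss, _ = _evaluate_loss_acc(model, X[35:], y[35:])
        assert loss == pytest.approx(min(history.val_loss), abs=1e-9)

    def test_deterministic_histories(self):
        X, y = _tiny_data(8)
        runs = []
        for _ in range(2):
            model = build_model(_tiny_arch(), seed=3)
            cfg = TrainConfig(learning_rate=0.01, batch_size=16, max_epochs=4,
                              early_stop_patience=10, seed=3)
            _, history = train_model(model, (X[:30], y[:30]), (X[30:], y[30:]), cfg)
            runs.append(history)
        assert runs[0].train_loss == runs[1].train_loss
        assert runs[0].val_loss == runs[1].val_loss

    def test_empty_dataset_rejected(self):
        X, y = _tiny_data(4)
        model = build_model(_tiny_arch(), seed=0)
        with pytest.raises(ValueError):
            train_model(model, (X[:0], y[:0]), (X, y), TrainConfig())


class TestSweep:
    def test_grid_shapes_mirror_published_tables(self):
        assert len(learning_rate_grid()) == 7
        assert [c.learning_rate for c in learning_rate_grid()] == [
            0.0006, 0.0007, 0.0008, 0.0009, 0.001, 0.0015, 0.002]
        assert all(c.batch_size == 150 for c in learning_rate_grid())
        assert [c.batch_size for c in batch_size_grid()] == [
            70, 90, 110, 130, 150, 170, 190]
        assert all(c.learning_rate == 0.001 for c in batch_size_grid())

    def test_sweep_rows_and_determinism(self):
        X, y = _tiny_data(8)
        grid = [TrainConfig(learning_rate=lr, batch_size=16, max_epochs=3,
                            early_stop_patience=5, seed=4)
                for lr in (0.001, 0.01, 0.05)]
        t1, _ = hyperparameter_sweep(grid, (X[:30], y[:30]), (X[30:], y[30:]),
                                     architecture=_tiny_arch(), model_seed=4)
        t2, _ = hyperparameter_sweep(grid, (X[:30], y[:30]), (X[30:], y[30:]),
                                     architecture=_tiny_arch(), model_seed=4)
        assert len(t1) == 3 and list(t1["learning_rate"]) == [0.001, 0.01, 0.05]
        assert t1["avg_loss"].tolist() == t2["avg_loss"].tolist()

    def test_singleton_grid_equals_single_run(self):
        X, y = _tiny_data(8)
        cfg = TrainConfig(learning_rate=0.01, batch_size=16, max_epochs=3,
                          early_stop_patience=5, seed=5)
        table, histories = hyperparameter_sweep(
            [cfg], (X[:30], y[:30]), (X[30:], y[30:]),
            architecture=_tiny_arch(), model_seed=5)
        model = build_model(_tiny_arch(), seed=5)
        _, history = train_model(model, (X[:30], y[:30]), (X[30:], y[30:]), cfg)
        assert histories[0].val_loss == history.val_loss
        assert table.loc[0, "avg_loss"] == pytest.approx(np.mean(history.val_loss))


class TestClassificationReport:
    def test_hand_counted_example(self):
        report = classification_report(["N", "A", "V"], ["N", "A", "A"])
        assert report.accuracy == pytest.approx(2 / 3)
        assert report.precision["A"] == pytest.approx(0.5)
        assert report.recall["A"] == pytest.approx(1.0)
        assert report.f1["A"] == pytest.approx(2 / 3)
        assert report.recall["V"] == 0.0

    def test_perfect_prediction(self):
        y = list("NAVLR") * 4
        report = classification_report(y, y)
        assert report.accuracy == 1.0
        assert np.all(np.diag(report.confusion) == 4)
        assert report.confusion.sum() == 20
        assert all(v == 1.0 for v in report.f1.values())

    def test_row_sums_are_supports(self):
        rng = np.random.default_rng(0)
        y_true = rng.choice(list("NAVLR"), 200)
        y_pred = rng.choice(list("NAVLR"), 200)
        report = classification_report(y_true, y_pred)
        for i, lab in enumerate(report.labels):
            assert report.confusion[i].sum() == int((y_true == lab).sum())
        assert report.confusion.sum() == 200

    def test_accuracy_is_support_weighted_recall(self):
        rng = np.random.default_rng(3)
        y_true = rng.choice(list("NAVLR"), 300)
        y_pred = rng.choice(list("NAVLR"), 300)
        report = classification_report(y_true, y_pred)
        supports = {lab: int((y_true == lab).sum()) for lab in report.labels}
        weighted = sum(report.recall[lab] * supports[lab]
                       for lab in report.labels) / 300
        assert report.accuracy == pytest.approx(weighted)

    def test_integer_label_inputs(self):
        report = classification_report([0, 1, 2, 3, 4], [0, 1, 2, 3, 4])
        assert report.accuracy == 1.0

    def test_absent_class_flagged(self):
        report = classification_report(["N", "N", "A"], ["N", "N", "N"])
        assert "V" in report.zero_division_classes
        assert report.precision["V"] == 0.0

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            classification_report(["N"], ["N", "A"])


class TestEndToEnd:
    def test_scaled_down_pipeline_accuracy(self, e2e_run):
        """500 segments/class, lr 0.001, batch 150: held-out accuracy >= 0.95."""
        _, history, report, _ = e2e_run
        assert report.accuracy >= 0.95
        assert max(history.val_accuracy) >= 0.95

    def test_confusion_conservation(self, e2e_run):
        _, _, report, test_set = e2e_run
        assert report.confusion.sum() == len(test_set)
        counts = test_set.class_counts
        for i, lab in enumerate(report.labels):
            assert report.confusion[i].sum() == counts[lab]

    def test_f1_is_harmonic_mean(self, e2e_run):
        _, _, report, _ = e2e_run
        for lab in report.labels:
            p, r = report.precision[lab], report.recall[lab]
            expected = 0.0 if p + r == 0 else 2 * p * r / (p + r)
            assert report.f1[lab] == pytest.approx(expected, abs=1e-12)
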