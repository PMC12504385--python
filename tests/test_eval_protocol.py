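"""Splits, metrics, confusion matrices, paired t-tests, and the training
loop's contracts (determinism, fixed epochs, zero-lr stability)."""

import dataclasses
import math

import numpy as np
import pytest
from scipy import stats as sstats

from mbcatt import (ModelConfig, TrainSpec, build_variant, confusion, evaluate,
                    kfold, metrics_from_confusion, paired_ttest,
                    run_experiment, split_within_subject, train)
from mbcatt.eval_protocol import ConfusionMatrix
from mbcatt.signal_store import BimodalWindow, WindowSet


def synthetic_window_set(n=100, n_classes=2, windows_per_trial=5, seed=0):
    """Lightweight labeled windows (tiny random patches) for split logic."""
    rng = np.random.default_rng(seed)
    windows = []
    for i in range(n):
        trial = i // windows_per_trial
        windows.append(BimodalWindow(
            eeg_patch=rng.standard_normal((2, 8)).astype(np.float32),
            fnirs_patch=rng.standard_normal((2, 4)).astype(np.float32),
            label=trial % n_classes, subject_id="S01",
            trial_id=trial, window_start_s=float(i)))
    names = [f"c{k}" for k in range(n_classes)]
    return WindowSet(windows, names, (5.0, 1.0))


class TestSplit:
    def test_80_20_disjoint_cover(self):
        ws = synthetic_window_set(100)
        tr, te = split_within_subject(ws, 0.8, seed=0)
        assert len(tr) == 80 and len(te) == 20
        starts = sorted([w.window_start_s for w in tr.windows]
                        + [w.window_start_s for w in te.windows])
        assert starts == sorted(w.window_start_s for w in ws.windows)

    def test_stratification(self):
        ws = synthetic_window_set(100, n_classes=2)
        tr, te = split_within_subject(ws, 0.8, seed=1)
        assert np.bincount(tr.labels()).tolist() == [40, 40]
        assert np.bincount(te.labels()).tolist() == [10, 10]

    def test_same_seed_identical(self):
        ws = synthetic_window_set(60)
        a = split_within_subject(ws, 0.8, seed=3)
        b = split_within_subject(ws, 0.8, seed=3)
        assert [w.window_start_s for w in a[0].windows] == \
               [w.window_start_s for w in b[0].windows]

    def test_trial_grouping_keeps_trials_whole(self):
        ws = synthetic_window_set(100, n_classes=2, windows_per_trial=5)
        tr, te = split_within_subject(ws, 0.8, seed=0, grouping="trial")
        assert set(tr.trial_ids()) & set(te.trial_ids()) == set()
        assert len(tr) + len(te) == 100

    def test_scarce_class_rejected(self):
        # 3 one-window trials -> class 1 has a single window
        ws = synthetic_window_set(3, n_classes=2, windows_per_trial=1)
        with pytest.raises(ValueError, match="at least 2"):
            split_within_subject(ws, 0.8, seed=0)


class TestKfold:
    def test_n10_k5_fold_sizes(self):
        ws = synthetic_window_set(10)
        folds = kfold(ws, k=5, seed=0)
        assert [len(te) for _, te in folds] == [2] * 5

    def test_n11_k5_balanced_remainder(self):
        folds = kfold(np.arange(11) % 2, k=5, seed=0)
        sizes = sorted(len(te) for _, te in folds)
        assert sizes == [2, 2, 2, 2, 3]

    def test_partition_property(self):
        rng = np.random.default_rng(5)
        for _ in range(25):
            n = int(rng.integers(5, 500))
            labels = rng.integers(0, 2, n)
            folds = kfold(labels, k=5, seed=int(rng.integers(1000)))
            tests = [te for _, te in folds]
            allidx = np.concatenate(tests)
            assert len(allidx) == n
            assert len(np.unique(allidx)) == n          # disjoint cover
            sizes = [len(t) for t in tests]
            assert max(sizes) - min(sizes) <= 1
            for tr, te in folds:
                assert set(tr) | set(te) == set(range(n))
                assert set(tr) & set(te) == set()

    def test_too_few_samples(self):
        with pytest.raises(ValueError):
            kfold(np.zeros(3), k=5)


class TestMetrics:
    def binary_cm(self, tp, tn, fp, fn):
        # rows true, cols predicted; class 1 is the positive class
        return ConfusionMatrix(np.array([[tn, fp], [fn, tp]]))

    def test_worked_binary_example(self):
        """TP=5 TN=4 FP=2 FN=1: accuracy 9/12, precision 5/7, recall 5/6,
        F1 = 2PR/(P+R) = 10/13."""
        rep = metrics_from_confusion(self.binary_cm(5, 4, 2, 1), "binary")
        assert rep.accuracy == pytest.approx(0.75)
        assert rep.precision == pytest.approx(5 / 7)
        assert rep.recall == pytest.approx(5 / 6)
        assert rep.f1 == pytest.approx(10 / 13)

    def test_perfect_predictions(self):
        cm = ConfusionMatrix(np.diag([7, 5, 9]))
        for avg in ("macro", "micro"):
            rep = metrics_from_confusion(cm, avg)
            assert rep.accuracy == rep.precision == rep.recall == rep.f1 == 1.0

    def test_micro_equals_accuracy_multiclass(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            cm = ConfusionMatrix(rng.integers(0, 20, (3, 3)))
            if cm.total == 0:
                continue
            rep = metrics_from_confusion(cm, "micro")
            assert rep.precision == pytest.approx(rep.accuracy)
            assert rep.recall == pytest.approx(rep.accuracy)

    def test_matches_counting_oracle_and_sklearn(self):
        """Exact agreement with a brute-force tally and with scikit-learn's
        macro averaging on random label vectors."""
        from sklearn.metrics import precision_recall_fscore_support

        rng = np.random.default_rng(1)
        for n_classes in (2, 3):
            for _ in range(25):
                n = int(rng.integers(10, 60))
                yt = rng.integers(0, n_classes, n)
                yp = rng.integers(0, n_classes, n)
                if len(np.unique(yt)) < n_classes or len(np.unique(yp)) < n_classes:
                    continue
                cm = confusion(yt, yp, n_classes)
                rep = metrics_from_confusion(cm, "macro")
                # brute-force per-class tally
                precs, recs = [], []
                for c in range(n_classes):
                    tp = int(np.sum((yt == c) & (yp == c)))
                    fp = int(np.sum((yt != c) & (yp == c)))
                    fn = int(np.sum((yt == c) & (yp != c)))
                    precs.append(tp / (tp + fp) if tp + fp else 0.0)
                    recs.append(tp / (tp + fn) if tp + fn else 0.0)
                assert rep.accuracy == pytest.approx(np.mean(yt == yp))
                assert rep.precision == pytest.approx(np.mean(precs))
                assert rep.recall == pytest.approx(np.mean(recs))
                p, r, f, _ = precision_recall_fscore_support(
                    yt, yp, average="macro", zero_division=0)
                assert rep.precision == pytest.approx(p)
                assert rep.recall == pytest.approx(r)
                assert rep.f1 == pytest.approx(f)

    def test_zero_denominator_contributes_zero(self, caplog):
        cm = ConfusionMatrix(np.array([[5, 0], [3, 0]]))  # class 1 never predicted
        rep = metrics_from_confusion(cm, "macro")
        assert rep.per_class["precision"][1] == 0.0
        assert math.isfinite(rep.f1)


class TestConfusion:
    def test_diagonal_when_perfect(self):
        y = np.array([0, 1, 2, 1, 0])
        cm = confusion(y, y, 3)
        np.testing.assert_array_equal(cm.counts, np.diag([2, 2, 1]))

    def test_single_misclassification(self):
        cm = confusion([0], [2], 3)
        expect = np.zeros((3, 3), dtype=int)
        expect[0, 2] = 1
        np.testing.assert_array_equal(cm.counts, expect)

    def test_row_sums_are_support(self):
        rng = np.random.default_rng(2)
        yt = rng.integers(0, 3, 200)
        yp = rng.integers(0, 3, 200)
        cm = confusion(yt, yp, 3)
        np.testing.assert_array_equal(cm.counts.sum(axis=1), np.bincount(yt))
        assert cm.total == 200

    def test_out_of_range_label_rejected(self):
        with pytest.raises(ValueError, match="out of range"):
            confusion([0, 3], [0, 1], 3)

    def test_heatmap_written(self, tmp_path):
        cm = confusion([0, 1, 1], [0, 1, 0], 2, ["BL", "WG"])
        out = cm.plot(tmp_path / "cm.png")
        assert out.exists() and out.stat().st_size > 0


class TestPairedTTest:
    def test_identical_vectors(self):
        res = paired_ttest([0.8, 0.9, 0.7], [0.8, 0.9, 0.7])
        assert res.t == 0.0 and res.p == 1.0 and res.mean_diff == 0.0

    def test_constant_nonzero_difference_flagged(self):
        res = paired_ttest([2, 3, 4, 5], [1, 2, 3, 4])
        assert res.zero_variance
        assert math.isnan(res.p)
        assert res.mean_diff == 1.0

    def test_textbook_example_closed_form_and_scipy(self):
        a = [0.9, 0.8, 0.95]
        b = [0.7, 0.6, 0.8]
        d = np.array(a) - np.array(b)
        t_hand = d.mean() / (d.std(ddof=1) / np.sqrt(3))
        res = paired_ttest(a, b)
        assert res.t == pytest.approx(t_hand)
        assert res.df == 2
        ref = sstats.ttest_rel(a, b)
        assert res.t == pytest.approx(ref.statistic)
        assert res.p == pytest.approx(ref.pvalue)

    def test_input_validation(self):
        with pytest.raises(ValueError):
            paired_ttest([1.0], [2.0])
        with pytest.raises(ValueError):
            paired_ttest([1, 2], [1, 2, 3])


@pytest.fixture(scope="module")
def trainable_windows(tiny_config):
    """Separable two-class windows matched to the tiny architecture."""
    rng = np.random.default_rng(8)
    windows = []
    for i in range(40):
        label = i % 2
        shift = 2.0 if label else -2.0
        windows.append(BimodalWindow(
            eeg_patch=(rng.standard_normal((12, 40)) + shift).astype(np.float32),
            fnirs_patch=(rng.standard_normal((12, 20)) - shift).astype(np.float32),
            label=label, subject_id="S01", trial_id=i // 4,
            window_start_s=float(i)))
    return WindowSet(windows, ["a", "b"], (5.0, 1.0))


class TestTrainLoop:
    def test_zero_lr_keeps_loss_constant(self, tiny_config, trainable_windows):
        # full-batch so batch-norm statistics do not change with shuffling
        model = build_variant("full", tiny_config, seed=0)
        spec = TrainSpec(learning_rate=0.0, epochs=3, batch_size=40, seed=0)
        train(model, trainable_windows, spec)
        losses = [h["loss"] for h in model.training_history]
        assert max(losses) - min(losses) < 1e-6

    def test_fixed_epoch_count_recorded(self, tiny_config, trainable_windows):
        model = build_variant("full", tiny_config, seed=0)
        train(model, trainable_windows, TrainSpec(epochs=4, batch_size=8, seed=0))
        assert [h["epoch"] for h in model.training_history] == [0, 1, 2, 3]

    def test_same_seed_identical_history(self, tiny_config, trainable_windows):
        histories = []
        for _ in range(2):
            model = build_variant("full", tiny_config, seed=5)
            train(model, trainable_windows,
                  TrainSpec(epochs=3, batch_size=8, seed=5))
            histories.append(model.training_history)
        assert histories[0] == histories[1]

    def test_learns_separable_data(self, tiny_config, trainable_windows):
        model = build_variant("full", tiny_config, seed=1)
        train(model, trainable_windows, TrainSpec(epochs=15, batch_size=8, seed=1))
        rep = evaluate(model, trainable_windows)
        assert rep.accuracy >= 0.95

    def test_empty_training_set_rejected(self, tiny_config):
        ws = WindowSet([], ["a", "b"], (5.0, 1.0))
        with pytest.raises(ValueError, match="empty"):
            train(build_variant("full", tiny_config), ws, TrainSpec(epochs=1))

    def test_spec_validation(self):
        with pytest.raises(ValueError):
            TrainSpec(epochs=0)
        with pytest.raises(ValueError):
            TrainSpec(learning_rate=-1.0)
        with pytest.raises(ValueError):
            TrainSpec(optimizer="sgd")


class TestRunExperiment:
    def test_cv5full_report_structure_and_rerun(self, tiny_config,
                                                trainable_windows):
        spec = TrainSpec(epochs=2, batch_size=8, seed=0)
        rep1 = run_experiment({"S01": trainable_windows}, tiny_config, spec,
                              protocol="cv5full", variants=("full",))
        folds = rep1["variants"]["full"]["folds"]
        assert len(folds) == 5
        assert set(rep1["variants"]["full"]["average"]) == \
               {"accuracy", "precision", "recall", "f1"}
        rep2 = run_experiment({"S01": trainable_windows}, tiny_config, spec,
                              protocol="cv5full", variants=("full",))
        assert rep1 == rep2

    def test_split_protocol_with_ablation_summary(self, tiny_config,
                                                  trainable_windows):
        spec = TrainSpec(epochs=2, batch_size=8, seed=0)
        rep = run_experiment({"S01": trainable_windows}, tiny_config, spec,
                             protocol="split8020_cv5train",
                             variants=("full", "eeg_only"))
        assert "S01" in rep["variants"]["full"]["per_subject"]
        assert "eeg_only" in rep["ablation"]
        assert "mean_accuracy_drop" in rep["ablation"]["eeg_only"]

    def test_unknown_protocol(self, tiny_config, trainable_windows):
        with pytest.raises(ValueError, match="protocol"):
            run_experiment({"S01": trainable_windows}, tiny_config,
                           TrainSpec(epochs=1), protocol="loocv")
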