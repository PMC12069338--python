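"""Training history, metric identities, K-fold partitioning and the
normality + paired-t comparison protocol."""

import numpy as np
import pytest
from scipy import stats
from sklearn.metrics import precision_recall_fscore_support

from msacnn.model import ModelConfig, build_msacnn_rm
from msacnn.preprocess import WindowSpec, WindowedDataset, one_hot
from msacnn.train_eval import (
    EvalReport, FoldPlan, TrainConfig, compare_models, evaluate, kfold_cv,
    make_fold_plan, paired_t, train,
)


def toy_dataset(n_per_class=12, classes=3, t=8, c=4, seed=0):
    """Windows whose channel amplitude profiles encode the class.

    Classes must differ in amplitude magnitude, not merely in which channel
    is hot: the (2,1)/(1,1) kernels of this architecture never span the
    channel axis and the heads pool over it, so pure channel-permutation
    codes are invisible to the model (by design)."""
    rng = np.random.default_rng(seed)
    windows, ids = [], []
    for g in range(classes):
        mean = np.zeros(c)
        mean[g % c] = 2.0 * (g + 1)
        for _ in range(n_per_class):
            w = rng.standard_normal((t, c)) * 0.3 + mean
            windows.append(w[:, :, None])
            ids.append(g)
    ids = np.array(ids)
    return WindowedDataset(
        windows=np.stack(windows), onehot_labels=one_hot(ids, classes),
        class_ids=ids, fs=100.0, spec=WindowSpec(80.0, 80.0))


def tiny_model(ds, variant="test3", seed=0, width=4):
    t, c, d = ds.windows.shape[1:]
    cfg = ModelConfig(num_classes=ds.n_classes, input_shape=(t, c, d),
                      width_scale=1.0, variant=variant, dropout_rate=0.0,
                      mrn_filters=(width,) * 4, acnl_filters=width,
                      stem_filters=width)
    return build_msacnn_rm(cfg, seed=seed)


class TestTrain:
    def test_history_has_one_entry_per_epoch(self):
        ds = toy_dataset(n_per_class=3)
        model = tiny_model(ds)
        hist = train(model, ds, ds, TrainConfig(epochs=1, batch_size=8, seed=0))
        assert len(hist["train_loss"]) == 1
        assert len(hist["val_acc"]) == 1

    def test_loss_decreases_on_separable_data(self):
        ds = toy_dataset()
        model = tiny_model(ds)
        hist = train(model, ds, None,
                     TrainConfig(epochs=30, batch_size=8, seed=1,
                                 track_best=False))
        assert hist["train_loss"][-1] < hist["train_loss"][0]

    def test_track_best_records_argmax_epoch(self):
        ds = toy_dataset(n_per_class=4)
        model = tiny_model(ds)
        hist = train(model, ds, ds, TrainConfig(epochs=5, batch_size=8, seed=2))
        assert hist["best_epoch"] == int(np.argmax(hist["val_acc"]))

    def test_label_width_mismatch_raises_before_training(self):
        ds = toy_dataset(n_per_class=2)
        t, c, d = ds.windows.shape[1:]
        cfg = ModelConfig(num_classes=7, input_shape=(t, c, d),
                          variant="test1", dropout_rate=0.0,
                          mrn_filters=(2, 2, 2, 2), acnl_filters=2,
                          stem_filters=2)
        model = build_msacnn_rm(cfg, seed=0)
        with pytest.raises(ValueError, match="label width"):
            train(model, ds, None, TrainConfig(epochs=1))


class TestEvaluate:
    def test_hand_computed_confusion_metrics(self):
        # confusion [[5,0],[1,4]]: acc 0.9; P0=5/6, R0=1; P1=1, R1=0.8
        rep = EvalReport.from_confusion([[5, 0], [1, 4]])
        assert rep.accuracy == pytest.approx(0.9)
        assert rep.per_class["precision"][0] == pytest.approx(5 / 6)
        assert rep.per_class["recall"][0] == pytest.approx(1.0)
        assert rep.per_class["precision"][1] == pytest.approx(1.0)
        assert rep.per_class["recall"][1] == pytest.approx(0.8)
        assert rep.f1 == pytest.approx((10 / 11 + 8 / 9) / 2)

    def test_macro_agrees_with_sklearn_when_all_classes_present(self, rng):
        y_true = rng.integers(0, 4, 200)
        y_pred = rng.integers(0, 4, 200)
        cm = np.zeros((4, 4), dtype=int)
        for t_, p_ in zip(y_true, y_pred):
            cm[t_, p_] += 1
        rep = EvalReport.from_confusion(cm)
        p, r, f, _ = precision_recall_fscore_support(
            y_true, y_pred, average="macro", zero_division=0)
        assert rep.precision == pytest.approx(p)
        assert rep.recall == pytest.approx(r)
        assert rep.f1 == pytest.approx(f)

    def test_micro_precision_equals_accuracy(self, rng):
        y_true = rng.integers(0, 5, 300)
        y_pred = rng.integers(0, 5, 300)
        cm = np.zeros((5, 5), dtype=int)
        for t_, p_ in zip(y_true, y_pred):
            cm[t_, p_] += 1
        rep = EvalReport.from_confusion(cm)
        assert rep.micro["precision"] == rep.micro["recall"] == rep.accuracy

    def test_perfect_predictions(self):
        rep = EvalReport.from_confusion(np.diag([7, 3, 5]))
        assert rep.accuracy == rep.precision == rep.recall == rep.f1 == 1.0

    def test_absent_class_excluded_from_macro(self):
        # class 1 never occurs in the data; always-correct on class 0
        rep = EvalReport.from_confusion([[10, 0], [0, 0]])
        assert rep.recall == pytest.approx(1.0)
        assert rep.accuracy == pytest.approx(1.0)

    def test_confusion_conservation(self):
        ds = toy_dataset(n_per_class=4)
        model = tiny_model(ds)
        rep = evaluate(model, ds)
        assert rep.confusion.sum() == ds.n
        np.testing.assert_array_equal(
            rep.confusion.sum(axis=1), np.bincount(ds.class_ids))
        assert rep.accuracy == pytest.approx(
            np.trace(rep.confusion) / rep.confusion.sum(), abs=1e-12)

    def test_empty_data_raises(self):
        ds = toy_dataset(n_per_class=2)
        model = tiny_model(ds)
        with pytest.raises(ValueError, match="empty"):
            evaluate(model, ds.subset(np.zeros(ds.n, dtype=bool)))


class TestKFold:
    def test_each_sample_tested_exactly_once(self):
        plan = make_fold_plan(np.repeat(np.arange(4), 25), K=5, seed=0)
        sizes = np.bincount(plan.fold_assignments, minlength=5)
        assert sizes.tolist() == [20] * 5

    def test_fold_sizes_differ_by_at_most_one(self):
        plan = make_fold_plan(np.repeat(np.arange(3), 34), K=5, seed=1)
        sizes = np.bincount(plan.fold_assignments, minlength=5)
        assert sizes.max() - sizes.min() <= 1

    def test_determinism(self):
        y = np.repeat(np.arange(4), 10)
        p1 = make_fold_plan(y, K=5, seed=3)
        p2 = make_fold_plan(y, K=5, seed=3)
        np.testing.assert_array_equal(p1.fold_assignments, p2.fold_assignments)

    def test_k_below_2_raises(self):
        with pytest.raises(ValueError, match="K"):
            make_fold_plan(np.zeros(10, dtype=int), K=1)

    def test_fold_plan_invariant_enforced(self):
        with pytest.raises(ValueError, match="differ"):
            FoldPlan(K=2, fold_assignments=np.array([0, 0, 0, 1]), seed=0)

    def test_cv_mean_is_mean_of_fold_accuracies(self):
        ds = toy_dataset(n_per_class=10)
        rep = kfold_cv(ds, 5, lambda k: tiny_model(ds, seed=k),
                       TrainConfig(epochs=3, batch_size=8, seed=0), seed=0)
        assert rep.accuracy == pytest.approx(
            np.mean([f["accuracy"] for f in rep.per_fold]))
        assert len(rep.per_fold) == 5
        assert rep.std_range[0] <= rep.std_range[1]

    def test_cv_beats_majority_baseline_on_separable_data(self):
        # Bayes-separable toy set: a sufficient model must clear the
        # majority-class rate (1/3) by a wide margin.
        ds = toy_dataset(n_per_class=15)
        rep = kfold_cv(ds, 5,
                       lambda k: tiny_model(ds, variant="test3", seed=k, width=8),
                       TrainConfig(epochs=40, batch_size=8, seed=0), seed=0)
        assert rep.accuracy >= 1 / 3 + 0.2


class TestCompareModels:
    def test_identical_samples_report_no_difference(self):
        a = [0.9, 0.91, 0.92, 0.93, 0.94]
        rep = compare_models(a, a)
        assert not rep.significant
        assert rep.t_p == 1.0
        assert "no difference" in rep.note

    def test_constant_offset_is_degenerate_and_significant(self):
        b = np.array([0.90, 0.91, 0.92, 0.93, 0.94])
        rep = compare_models(b + 0.01, b)
        assert rep.mean_diff == pytest.approx(0.01)
        assert np.isinf(rep.t_stat) and rep.t_p == 0.0
        assert rep.significant and "degenerate" in rep.note

    def test_paired_t_matches_scipy_reference(self, rng):
        a = rng.normal(0.9, 0.02, 30)
        b = a + rng.normal(0.01, 0.02, 30)
        t_ours, p_ours = paired_t(a, b)
        ref = stats.ttest_rel(a, b)
        assert t_ours == pytest.approx(ref.statistic, abs=1e-10)
        assert p_ours == pytest.approx(ref.pvalue, abs=1e-10)

    def test_textbook_closed_form(self):
        # d = [1, 2, 3]: mean 2, sd 1, t = 2/(1/sqrt(3)) = 2*sqrt(3)
        a = np.array([2.0, 4.0, 6.0])
        b = np.array([1.0, 2.0, 3.0])
        t, p = paired_t(a, b)
        assert t == pytest.approx(2 * np.sqrt(3))
        assert p == pytest.approx(2 * stats.t.sf(2 * np.sqrt(3), df=2))

    def test_normality_rejection_flags_t_test(self, rng):
        b = np.zeros(20)
        a = np.concatenate([np.full(19, 0.001), [5.0]])  # extreme outlier
        rep = compare_models(a, b)
        assert rep.normality_rejected
        assert "unreliable" in rep.note
        assert not rep.significant

    def test_unequal_lengths_raise(self):
        with pytest.raises(ValueError, match="length"):
            compare_models([0.1, 0.2, 0.3], [0.1, 0.2])
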