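import numpy as np
import pytest

from eegfst import TrainConfig, compute_metrics, make_folds, run_cv, trials_to_samples
from eegfst.model import CNNConfig


class TestFolds:
    def test_forty_trials_five_folds_of_eight(self):
        folds = make_folds(range(40), 5, seed=0)
        assert [len(f) for f in folds] == [8, 8, 8, 8, 8]

    def test_partition_properties(self):
        folds = make_folds(range(23), 5, seed=1)
        sizes = [len(f) for f in folds]
        assert max(sizes) - min(sizes) <= 1
        union = np.concatenate(folds)
        assert sorted(union) == list(range(23))

    def test_seed_determinism(self):
        a = make_folds(range(40), 5, seed=9)
        b = make_folds(range(40), 5, seed=9)
        for x, y in zip(a, b):
            np.testing.assert_array_equal(x, y)

    def test_more_folds_than_trials_rejected(self):
        with pytest.raises(ValueError):
            make_folds(range(3), 5)


class TestMetrics:
    def test_confusion_example_arithmetic(self):
        # confusion [[9,1],[2,8]]: 9+8 correct of 20
        y_true = [0] * 10 + [1] * 10
        y_pred = [0] * 9 + [1] + [0] * 2 + [1] * 8
        rep = compute_metrics(y_true, y_pred, ("low", "high"))
        np.testing.assert_array_equal(rep.confusion, [[9, 1], [2, 8]])
        assert rep.accuracy == pytest.approx(0.85)
        assert rep.per_class["low"]["precision"] == pytest.approx(9 / 11)
        assert rep.per_class["low"]["recall"] == pytest.approx(0.9)
        assert rep.per_class["low"]["f1"] == pytest.approx(2 * (9 / 11) * 0.9 / (9 / 11 + 0.9))

    def test_perfect_predictions(self):
        rep = compute_metrics([0, 1, 2], [0, 1, 2], ("a", "b", "c"))
        assert rep.accuracy == 1.0
        assert all(v["f1"] == 1.0 for v in rep.per_class.values())

    def test_degenerate_single_class_predictor(self):
        rep = compute_metrics([0] * 5 + [1] * 5, [0] * 10, ("low", "high"))
        assert rep.accuracy == 0.5
        assert rep.per_class["high"]["recall"] == 0.0

    def test_absent_class_marked_undefined(self):
        rep = compute_metrics([0, 0, 1], [0, 0, 1], ("a", "b", "c"))
        assert np.isnan(rep.per_class["c"]["precision"])

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            compute_metrics([0, 1], [0], ("a", "b"))

    def test_std_is_sample_standard_deviation(self):
        from eegfst.train import EvalReport

        rep = EvalReport(
            fold_accuracies=[0.8, 0.9, 1.0],
            confusion=np.eye(2, dtype=int),
            class_names=("a", "b"),
            per_class={},
        )
        assert rep.std_acc == pytest.approx(np.std([0.8, 0.9, 1.0], ddof=1))
        assert rep.mean_acc == pytest.approx(0.9)


@pytest.fixture(scope="module")
def tiny_cv_inputs(small_trials, deap_layout):
    trials, classes = small_trials
    return trials, [int(c) for c in classes], deap_layout


class TestPipelineCV:
    def test_samples_inherit_trial_label_and_id(self, tiny_cv_inputs):
        trials, labels, layout = tiny_cv_inputs
        samples = trials_to_samples(trials, labels, layout, two_t=4)
        by_trial = {}
        for s in samples:
            by_trial.setdefault(s.trial_id, set()).add(s.label)
        assert set(by_trial) == {t.trial_id for t in trials}
        for tid, labs in by_trial.items():
            assert labs == {labels[tid]}

    def test_no_leakage_between_folds(self, tiny_cv_inputs):
        trials, labels, layout = tiny_cv_inputs
        folds = make_folds([t.trial_id for t in trials], 3, seed=2)
        samples = trials_to_samples(trials, labels, layout, two_t=4)
        for test_ids in folds:
            train_ids = {s.trial_id for s in samples if s.trial_id not in test_ids}
            assert train_ids.isdisjoint(set(test_ids))

    def test_run_cv_reproducible_with_same_seed(self, tiny_cv_inputs):
        trials, labels, layout = tiny_cv_inputs
        cfg = CNNConfig(
            conv1_filters=4, conv2_filters=8, pointwise_filters=8, dense_units=16,
        )
        kw = dict(
            cnn_cfg=cfg,
            train_cfg=TrainConfig(epochs=2, batch_size=16, k_folds=2, seed=5),
            hidden=8,
            two_t=4,
        )
        r1 = run_cv(trials, labels, layout, **kw)
        r2 = run_cv(trials, labels, layout, **kw)
        assert r1.fold_accuracies == pytest.approx(r2.fold_accuracies, abs=1e-6)
        np.testing.assert_array_equal(r1.confusion, r2.confusion)

    def test_report_consistency(self, tiny_cv_inputs):
        trials, labels, layout = tiny_cv_inputs
        cfg = CNNConfig(
            conv1_filters=4, conv2_filters=8, pointwise_filters=8, dense_units=16,
        )
        rep = run_cv(
            trials, labels, layout,
            cnn_cfg=cfg,
            train_cfg=TrainConfig(epochs=1, batch_size=16, k_folds=2, seed=0),
            hidden=8,
            two_t=4,
        )
        n_samples = len(trials_to_samples(trials, labels, layout, two_t=4))
        assert rep.confusion.sum() == n_samples
        assert len(rep.fold_losses) == len(rep.fold_accuracies)

    def test_single_class_training_fold_skipped(self, deap_layout, small_trials):
        trials, _ = small_trials
        labels = [0, 0, 0, 0, 0, 1]  # one lone positive trial
        cfg = CNNConfig(
            conv1_filters=4, conv2_filters=8, pointwise_filters=8, dense_units=16,
        )
        with pytest.warns(UserWarning, match="single class"):
            rep = run_cv(
                trials, labels, deap_layout,
                cnn_cfg=cfg,
                train_cfg=TrainConfig(epochs=1, batch_size=16, k_folds=6, seed=1),
                hidden=8,
                two_t=4,
            )
        assert len(rep.skipped_folds) >= 1
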