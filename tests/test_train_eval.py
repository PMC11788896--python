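"""Schedule, loss, confusion matrix / metrics, and the training loop."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from hpfasternet.train_eval import (ConfusionMatrix, LRSchedule, TrainConfig,
                                    batch_cross_entropy, confusion_matrix,
                                    cross_entropy, lr_at_epoch, metrics,
                                    softmax, train)


class TestSchedule:
    @pytest.mark.parametrize("n,expected", [
        (1, 0.01), (4, 0.01), (5, 0.0085), (13, 0.00614125),
    ])
    def test_closed_form_values(self, n, expected):
        assert lr_at_epoch(n) == pytest.approx(expected, rel=1e-12)

    def test_100_epochs_have_25_plateaus_non_increasing(self):
        lrs = [lr_at_epoch(n) for n in range(1, 101)]
        assert len(set(lrs)) == 25
        assert all(a >= b for a, b in zip(lrs, lrs[1:]))
        # constant within each 4-epoch block
        for i in range(0, 100, 4):
            assert len(set(lrs[i:i + 4])) == 1

    def test_invalid_epoch_and_schedule_rejected(self):
        with pytest.raises(ValueError):
            lr_at_epoch(0)
        with pytest.raises(ValueError):
            LRSchedule(d=1.5)
        with pytest.raises(ValueError):
            LRSchedule(p=0)


class TestCrossEntropy:
    @pytest.mark.parametrize("p,c,expected", [
        ([0.5, 0.5], 1, 0.693147),
        ([0.0, 1.0], 1, 0.0),
        ([0.2, 0.7, 0.1], 1, 0.356675),
    ])
    def test_values(self, p, c, expected):
        assert cross_entropy(np.array(p), c) == pytest.approx(expected,
                                                              abs=1e-6)

    def test_unnormalized_rejected(self):
        with pytest.raises(ValueError):
            cross_entropy(np.array([0.5, 0.6]), 0)

    @given(st.lists(st.floats(0.01, 10.0), min_size=2, max_size=8),
           st.data())
    @settings(max_examples=40, deadline=None)
    def test_nonnegative_zero_iff_certain(self, raw, data):
        p = np.array(raw) / np.sum(raw)
        c = data.draw(st.integers(0, len(p) - 1))
        assert cross_entropy(p, c) >= 0.0
        onehot = np.zeros(len(p))
        onehot[c] = 1.0
        assert cross_entropy(onehot, c) == 0.0

    def test_batch_gradient_is_softmax_minus_onehot(self):
        logits = np.array([[1.0, 2.0, 0.5], [0.1, 0.1, 3.0]])
        targets = np.array([1, 2])
        loss, grad = batch_cross_entropy(logits, targets)
        probs = softmax(logits)
        expect = probs.copy()
        expect[[0, 1], targets] -= 1
        assert np.allclose(grad, expect / 2, atol=1e-6)
        assert loss == pytest.approx(
            -np.log(probs[[0, 1], targets]).mean(), abs=1e-9)


class TestConfusionMatrix:
    def test_perfect_predictions_are_diagonal(self):
        cm = confusion_matrix([0, 1, 2, 1], [0, 1, 2, 1], 3)
        assert np.array_equal(cm.counts, np.diag([1, 2, 1]))

    def test_binary_counts_reconstructed(self):
        truth = [1] * 55 + [0] * 45
        pred = [1] * 50 + [0] * 5 + [1] * 10 + [0] * 35
        cm = confusion_matrix(pred, truth, 2)
        assert cm.one_vs_rest(1) == (50, 10, 5, 35)

    def test_row_sums_are_class_totals_and_tp_fp_fn_tn_sum(self, rng):
        truth = rng.integers(0, 5, 200)
        pred = rng.integers(0, 5, 200)
        cm = confusion_matrix(pred, truth, 5)
        assert np.array_equal(cm.counts.sum(axis=1), np.bincount(truth, minlength=5))
        for c in range(5):
            assert sum(cm.one_vs_rest(c)) == 200

    def test_out_of_range_labels_rejected(self):
        with pytest.raises(ValueError):
            confusion_matrix([0, 3], [0, 1], 3)
        with pytest.raises(ValueError):
            confusion_matrix([0], [0, 1], 2)


class TestMetrics:
    def test_binary_example(self):
        cm = ConfusionMatrix(np.array([[35, 10], [5, 50]]))
        rep = metrics(cm)
        assert rep.accuracy[1] == pytest.approx(0.85)
        assert rep.precision[1] == pytest.approx(0.8333, abs=1e-4)
        assert rep.recall[1] == pytest.approx(0.9091, abs=1e-4)
        assert rep.f1[1] == pytest.approx(0.8696, abs=1e-4)

    def test_diagonal_matrix_scores_one(self):
        rep = metrics(ConfusionMatrix(np.diag([3, 4, 5])))
        for arr in (rep.accuracy, rep.precision, rep.recall, rep.f1):
            assert np.allclose(arr, 1.0)
        assert rep.micro_accuracy == 1.0

    def test_zero_denominator_warns_and_reports_zero(self):
        cm = ConfusionMatrix(np.array([[5, 0], [3, 0]]))  # class 1 never predicted
        with pytest.warns(UserWarning):
            rep = metrics(cm)
        assert rep.precision[1] == 0.0

    @given(st.integers(2, 25), st.integers(0, 10_000))
    @settings(max_examples=25, deadline=None)
    def test_f1_is_harmonic_mean_of_p_and_r(self, m, seed):
        rng = np.random.default_rng(seed)
        truth = rng.integers(0, m, 300)
        pred = rng.integers(0, m, 300)
        cm = confusion_matrix(pred, truth, m)
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rep = metrics(cm)
        for c in range(m):
            p, r = rep.precision[c], rep.recall[c]
            if p + r > 0:
                assert rep.f1[c] == pytest.approx(2 * p * r / (p + r),
                                                  abs=1e-12)

    def test_agrees_with_sklearn_oracle(self, rng):
        from sklearn.metrics import (accuracy_score,
                                     precision_recall_fscore_support)

        truth = rng.integers(0, 7, 400)
        pred = rng.integers(0, 7, 400)
        cm = confusion_matrix(pred, truth, 7)
        rep = metrics(cm)
        p, r, f1, _ = precision_recall_fscore_support(
            truth, pred, labels=range(7), zero_division=0)
        assert np.allclose(rep.precision, p, atol=1e-12)
        assert np.allclose(rep.recall, r, atol=1e-12)
        assert np.allclose(rep.f1, f1, atol=1e-12)
        assert rep.micro_accuracy == pytest.approx(
            accuracy_score(truth, pred), abs=1e-12)


class TestTraining:
    def test_history_contract_and_lr_column(self, tiny_trained):
        _, res, _ = tiny_trained
        assert len(res.history) == 3
        for rec in res.history:
            assert rec.lr == lr_at_epoch(rec.epoch)
            assert np.isfinite(rec.train_loss)

    def test_same_seed_gives_identical_curves(self):
        from hpfasternet import TrainConfig, tiny_config
        from hpfasternet.nets import Network
        from hpfasternet.synth_seeds import make_arrays

        data, _ = make_arrays(3, scenes_per_class=1, seed=11, rows=4, cols=6,
                              input_size=32)
        curves = []
        for _ in range(2):
            net = Network(tiny_config("hpfasternet", 3, 32), seed=11)
            res = train(net, data, TrainConfig(epochs=2, batch_size=16,
                                               seed=11))
            curves.append([(r.train_loss, r.val_loss, r.val_accuracy)
                           for r in res.history])
        assert curves[0] == curves[1]

    def test_class_count_mismatch_rejected(self, tiny_trained):
        net, _, data = tiny_trained
        bad = dict(data)
        bad["train"] = (data["train"][0], data["train"][1] + 5)
        with pytest.raises(ValueError):
            train(net, bad, TrainConfig(epochs=1, batch_size=16, seed=0))

    def test_empty_split_rejected(self, tiny_trained):
        net, _, data = tiny_trained
        bad = dict(data)
        bad["val"] = (data["val"][0][:0], data["val"][1][:0])
        with pytest.raises(ValueError):
            train(net, bad, TrainConfig(epochs=1, batch_size=16, seed=0))

    def test_best_state_selected_by_validation_accuracy(self, tiny_trained):
        _, res, _ = tiny_trained
        accs = [r.val_accuracy for r in res.history]
        assert res.best_val_accuracy == max(accs)
        assert res.best_epoch == accs.index(max(accs)) + 1  # earliest tie
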