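"""Training protocol, metrics, cross-validation and ablation harness."""

import math

import numpy as np
import pytest

from strokefusion.model import ArmFlags
from strokefusion.nn import Adam, Linear, Tensor, softmax_cross_entropy
from strokefusion.synthetic import generate_cohort
from strokefusion.train_eval import (ConfusionCounts, TrainConfig,
                                     compute_metrics, confusion_counts,
                                     cross_validate, evaluate,
                                     f1_from_precision_recall,
                                     prepare_dataset, roc_auc, run_ablation,
                                     split_cohort, stratified_patient_folds,
                                     train)

TINY = TrainConfig(image_size=32, batch_size=8, epochs=1, profile="desk",
                   seed=0, arms=ArmFlags(False, False, False))


@pytest.fixture(scope="module")
def tiny_cohort():
    return generate_cohort(8, slices_per_patient=2, seed=3, image_size=32)


class TestTrain:
    def test_one_epoch_smoke(self, tiny_cohort):
        ds = prepare_dataset(tiny_cohort)
        model, history = train(TINY, ds)
        assert len(history["loss"]) == 1
        assert math.isfinite(history["loss"][0])

    def test_separable_toy_loss_monotone(self):
        # classifier head alone on linearly separable 2-feature data:
        # logistic loss decreases monotonically per epoch
        rng = np.random.default_rng(0)
        x = np.concatenate([rng.normal(-2, 0.3, size=(20, 2)),
                            rng.normal(2, 0.3, size=(20, 2))])
        y = np.array([0] * 20 + [1] * 20)
        head = Linear(2, 2, np.random.default_rng(1))
        opt = Adam(head.parameters(), lr=0.01)
        losses = []
        for _ in range(20):
            loss = softmax_cross_entropy(head(Tensor(x)), y)
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(loss.item())
        assert all(b < a for a, b in zip(losses, losses[1:]))

    def test_same_seed_same_validation_accuracy(self, tiny_cohort):
        tr, te = split_cohort(tiny_cohort, 0.25, seed=0)
        tds = prepare_dataset(tr)
        eds = prepare_dataset(te, train_samples=tr)
        accs = []
        for _ in range(2):
            model, history = train(TINY, tds, eds)
            accs.append(history["val_accuracy"][-1])
        assert accs[0] == accs[1]

    def test_patient_overlap_between_splits_raises(self, tiny_cohort):
        ds = prepare_dataset(tiny_cohort)
        with pytest.raises(ValueError, match="appear in both"):
            train(TINY, ds, ds)


class TestConfusionCounts:
    def test_perfect_prediction(self):
        c = confusion_counts((1, 1, 0, 0), (1, 1, 0, 0))
        assert (c.tp, c.tn, c.fp, c.fn) == (2, 2, 0, 0)

    def test_manual_tally_oracle(self):
        c = confusion_counts((1, 1, 1, 0, 0, 0, 0, 1, 1, 0),
                             (1, 1, 0, 1, 0, 0, 0, 0, 1, 0))
        assert (c.tp, c.fn, c.fp, c.tn) == (3, 2, 1, 4)

    def test_degenerate_all_positive_predictor(self):
        c = confusion_counts([0] * 7, [1] * 7)
        assert (c.fp, c.tp, c.tn, c.fn) == (7, 0, 0, 0)

    def test_non_binary_raises(self):
        with pytest.raises(ValueError, match="non-binary"):
            confusion_counts((0, 1, 2), (0, 1, 1))


class TestComputeMetrics:
    def test_worked_example(self):
        m = compute_metrics(ConfusionCounts(tp=3, fp=1, tn=4, fn=2))
        assert m.accuracy == 0.7
        assert m.precision == 0.75
        assert m.sensitivity == 0.6
        assert m.specificity == 0.8
        assert abs(m.f1 - 2 * 0.75 * 0.6 / 1.35) < 1e-12

    def test_published_f1_consistency(self):
        # the headline row's F1 follows from its precision and recall
        assert abs(f1_from_precision_recall(87.26, 95.21) - 91.06) < 0.01

    def test_perfect_confusion_all_ones(self):
        m = compute_metrics(ConfusionCounts(tp=5, fp=0, tn=5, fn=0))
        for v in (m.accuracy, m.precision, m.sensitivity, m.specificity,
                  m.f1):
            assert v == 1.0

    def test_zero_denominator_flagged_not_zeroed(self):
        m = compute_metrics(ConfusionCounts(tp=0, fp=0, tn=4, fn=2))
        assert math.isnan(m.precision)
        assert "precision" in m.undefined
        assert m.accuracy == 4 / 6

    def test_all_zero_counts_raise(self):
        with pytest.raises(ValueError):
            compute_metrics(ConfusionCounts(0, 0, 0, 0))

    def test_exact_agreement_with_counting_oracle(self, rng):
        for _ in range(1000):
            n = rng.integers(4, 40)
            yt = rng.integers(0, 2, size=n)
            yp = rng.integers(0, 2, size=n)
            c = confusion_counts(yt, yp)
            # independent oracle: plain python counting
            tp = sum(1 for a, b in zip(yt, yp) if a == 1 and b == 1)
            fp = sum(1 for a, b in zip(yt, yp) if a == 0 and b == 1)
            tn = sum(1 for a, b in zip(yt, yp) if a == 0 and b == 0)
            fn = sum(1 for a, b in zip(yt, yp) if a == 1 and b == 0)
            assert (c.tp, c.fp, c.tn, c.fn) == (tp, fp, tn, fn)
            m = compute_metrics(c)
            assert m.accuracy == (tp + tn) / n
            if tp + fp:
                assert m.precision == tp / (tp + fp)


class TestRocAuc:
    def test_perfect_separation(self):
        assert roc_auc([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1]) == 1.0

    def test_all_ties(self):
        assert roc_auc([0.5] * 6, [0, 1, 0, 1, 0, 1]) == 0.5

    def test_matches_exhaustive_pairwise_oracle(self, rng):
        for _ in range(20):
            scores = rng.normal(size=50)
            scores[rng.random(50) < 0.3] = 0.0      # force ties
            labels = rng.integers(0, 2, size=50)
            if labels.min() == labels.max():
                continue
            pos = scores[labels == 1]
            neg = scores[labels == 0]
            wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
            oracle = wins / (len(pos) * len(neg))
            assert abs(roc_auc(scores, labels) - oracle) < 1e-12

    def test_monotone_transform_invariance(self, rng):
        scores = rng.normal(size=30)
        labels = rng.integers(0, 2, size=30)
        labels[0], labels[1] = 0, 1
        a = roc_auc(scores, labels)
        assert roc_auc(np.exp(scores), labels) == a
        assert roc_auc(3 * scores - 7, labels) == a

    def test_single_class_raises(self):
        with pytest.raises(ValueError, match="both classes"):
            roc_auc([0.1, 0.9], [1, 1])


class TestCrossValidation:
    def test_folds_partition_patients(self):
        pids = [f"P{i}" for i in range(100)]
        labels = [i % 2 for i in range(100)]
        folds = stratified_patient_folds(pids, labels, k=5, seed=0)
        seen = np.concatenate(folds)
        assert len(seen) == 100
        assert len(set(seen)) == 100          # each patient exactly once

    def test_folds_depend_only_on_inputs(self):
        pids = [f"P{i}" for i in range(20)]
        labels = [i % 2 for i in range(20)]
        a = stratified_patient_folds(pids, labels, 4, seed=3)
        b = stratified_patient_folds(pids, labels, 4, seed=3)
        for fa, fb in zip(a, b):
            np.testing.assert_array_equal(fa, fb)
        c = stratified_patient_folds(pids, labels, 4, seed=4)
        assert any(not np.array_equal(fa, fc) for fa, fc in zip(a, c))

    def test_too_few_patients_per_class_raises(self):
        with pytest.raises(ValueError, match="at least"):
            stratified_patient_folds(["a", "b", "c"], [0, 0, 1], k=2, seed=0)

    def test_cross_validate_summary_matches_fold_arithmetic(self):
        cohort = generate_cohort(10, slices_per_patient=1, seed=5,
                                 image_size=32)
        report = cross_validate(TINY, cohort, k=2, seed=0)
        accs = [f["accuracy"] for f in report.per_fold]
        assert len(accs) == 2
        assert abs(report.mean["accuracy"] - np.mean(accs)) < 1e-12
        assert abs(report.std["accuracy"] - np.std(accs)) < 1e-12

    def test_metric_std_zero_for_identical_folds(self):
        from strokefusion.train_eval import _fold_summary
        fold = {"accuracy": 0.8, "precision": 0.7, "sensitivity": 0.6,
                "specificity": 0.9, "f1": 0.65, "auc": 0.85}
        mean, std = _fold_summary([dict(fold), dict(fold), dict(fold)])
        assert all(abs(v) < 1e-12 for v in std.values())
        assert abs(mean["accuracy"] - 0.8) < 1e-12


class TestAblation:
    def test_table_structure_and_parameter_counts(self):
        cohort = generate_cohort(8, slices_per_patient=1, seed=6,
                                 image_size=32)
        rows = run_ablation(cohort, TINY, seeds=(0,), test_fraction=0.25)
        assert [r["arm"] for r in rows] == [1, 2, 3, 4]
        assert [(r["ms"], r["glam"], r["mlp"]) for r in rows] == [
            (False, False, False), (True, False, False),
            (True, True, False), (True, True, True)]
        assert rows[3]["n_parameters"] > rows[0]["n_parameters"]
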