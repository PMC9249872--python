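"""Class weights, LOOCV folding, undersampling, OvO training and metrics."""

import numpy as np
import pytest

from tstms.classify import (
    Dataset,
    FoldResult,
    class_weights,
    evaluate,
    loocv_folds,
    run_loocv,
    subset_accuracy,
    train_ovo,
    undersample_test,
)

FAST = {"n_estimators": 5, "colsample_bytree": 1.0}


class TestClassWeights:
    def test_study_counts(self):
        w = class_weights({"S": 27, "N": 30, "D": 26, "F": 22, "A": 25})
        assert w["F"] == pytest.approx(130 / (5 * 22))
        assert w["N"] == pytest.approx(130 / (5 * 30))

    def test_balanced_counts_give_unit_weights(self):
        w = class_weights({"A": 10, "N": 10})
        assert all(v == 1.0 for v in w.values())

    def test_two_class_example(self):
        w = class_weights({"A": 10, "B": 30})
        assert w["A"] == pytest.approx(2.0)
        assert w["B"] == pytest.approx(2 / 3)

    def test_zero_count_rejected(self):
        with pytest.raises(ValueError):
            class_weights({"A": 0, "B": 5})


def _dataset(n_subjects=3, per_class=2, n_features=20, classes=("A", "N"),
             seed=0):
    rng = np.random.default_rng(seed)
    rows, y, subj = [], [], []
    for s in range(n_subjects):
        for c in classes:
            for _ in range(per_class):
                offset = 3.0 * classes.index(c)
                rows.append(rng.normal(offset, 1.0, n_features))
                y.append(c)
                subj.append(f"S{s}")
    return Dataset(X=np.array(rows), y=np.array(y), subjects=np.array(subj),
                   gender=np.array(["F", "M"] * (len(y) // 2)))


class TestLoocvFolds:
    def test_one_fold_per_subject_with_disjoint_train(self):
        ds = _dataset(3)
        folds = list(loocv_folds(ds))
        assert len(folds) == 3
        for train, test, subject in folds:
            assert set(train) & set(test) == set()
            assert set(ds.subjects[test]) == {subject}
            assert subject not in set(ds.subjects[train])
            assert len(train) == len(ds.y) - len(test)

    def test_single_subject_rejected(self):
        ds = _dataset(3)
        ds.subjects[:] = "S0"
        with pytest.raises(ValueError):
            list(loocv_folds(ds))

    def test_subject_with_one_class_rejected(self):
        with pytest.raises(ValueError, match="fewer than 2 classes"):
            Dataset(X=np.zeros((3, 2)), y=np.array(["A", "A", "N"]),
                    subjects=np.array(["S0", "S0", "S1"]))


class TestUndersampleTest:
    def test_study_counts_reduced_to_22(self):
        labels = np.concatenate([["S"] * 27, ["N"] * 30, ["D"] * 26,
                                 ["F"] * 22, ["A"] * 25])
        sel = undersample_test(labels, seed=0)
        counts = {c: int(np.sum(labels[sel] == c)) for c in "SNDFA"}
        assert all(v == 22 for v in counts.values())

    def test_balanced_input_is_identity(self):
        labels = np.array(["A"] * 4 + ["N"] * 4)
        sel = undersample_test(labels, seed=1)
        assert sorted(sel) == list(range(8))

    def test_seed_determinism(self):
        labels = np.array(["A"] * 9 + ["N"] * 4)
        np.testing.assert_array_equal(undersample_test(labels, seed=5),
                                      undersample_test(labels, seed=5))


class TestTrainOvo:
    def test_five_classes_yield_ten_binary_models(self):
        ds = _dataset(2, per_class=2, classes=("A", "D", "F", "S", "N"))
        model = train_ovo(ds.X, ds.y, hyperparams=FAST)
        assert model.n_binary == 10

    def test_two_classes_yield_one_model(self):
        ds = _dataset(2)
        model = train_ovo(ds.X, ds.y, hyperparams=FAST)
        assert model.n_binary == 1

    def test_separable_classes_fit_training_data(self):
        ds = _dataset(4, per_class=4, seed=3)
        model = train_ovo(ds.X, ds.y, hyperparams={"n_estimators": 30,
                                                   "colsample_bytree": 1.0})
        assert np.mean(model.predict(ds.X) == ds.y) == 1.0

    def test_probabilities_are_simplex_rows(self):
        ds = _dataset(3, classes=("A", "D", "N"))
        model = train_ovo(ds.X, ds.y, hyperparams=FAST)
        proba = model.predict_proba(ds.X)
        assert proba.shape == (len(ds.y), 3)
        assert np.all(proba >= 0)
        np.testing.assert_allclose(proba.sum(axis=1), 1.0, atol=1e-9)

    def test_undersized_class_rejected(self):
        X = np.zeros((3, 4))
        with pytest.raises(ValueError, match="< 2"):
            train_ovo(X, np.array(["A", "A", "N"]), hyperparams=FAST)


class TestSubsetAccuracy:
    def test_exact_and_partial_match(self):
        y = np.array(list("ADFSN"))
        assert subset_accuracy(y, y) == 1.0
        y10 = np.array(list("AAAAADDDDD"))
        pred = np.array(list("AAAAANNNNN"))
        assert subset_accuracy(pred, y10) == 0.5

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            subset_accuracy(np.array([]), np.array([]))


def _fold(proba, y_true, classes=("A", "N")):
    proba = np.asarray(proba, dtype=float)
    y_true = np.asarray(y_true)
    preds = np.asarray(classes)[np.argmax(proba, axis=1)]
    return FoldResult("S0", proba, preds, y_true, list(classes))


class TestEvaluate:
    def test_perfect_probabilities(self):
        fold = _fold([[0.9, 0.1], [0.8, 0.2], [0.1, 0.9]],
                     ["A", "A", "N"])
        rep = evaluate([fold])
        assert rep.roc_auc == {"A": 1.0, "N": 1.0}
        assert rep.subset_accuracy == 1.0
        np.testing.assert_allclose(np.diag(rep.confusion_percent), 100.0)

    def test_auc_equals_mann_whitney_count(self):
        """One-vs-rest AUC equals the pairwise rank statistic, brute force."""
        proba = np.array([[0.9, 0.1], [0.6, 0.4], [0.55, 0.45],
                          [0.7, 0.3], [0.2, 0.8]])
        y = np.array(["A", "A", "N", "N", "N"])
        rep = evaluate([_fold(proba, y)])
        pos = proba[y == "A", 0]
        neg = proba[y == "N", 0]
        wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
        assert rep.roc_auc["A"] == pytest.approx(wins / (len(pos) * len(neg)))

    def test_random_scores_give_half_auc(self):
        rng = np.random.default_rng(0)
        n = 4000
        p = rng.uniform(size=n)
        proba = np.column_stack([p, 1 - p])
        rep = evaluate([_fold(proba, rng.choice(["A", "N"], size=n))])
        assert rep.roc_auc["A"] == pytest.approx(0.5, abs=0.03)
        assert rep.subset_accuracy == pytest.approx(0.5, abs=0.05)

    def test_metrics_invariant_to_trial_order(self):
        rng = np.random.default_rng(3)
        proba = rng.dirichlet([1, 1], size=12)
        y = rng.choice(["A", "N"], size=12)
        rep1 = evaluate([_fold(proba, y)])
        perm = rng.permutation(12)
        rep2 = evaluate([_fold(proba[perm], y[perm])])
        assert rep1.roc_auc == rep2.roc_auc
        assert rep1.subset_accuracy == rep2.subset_accuracy
        np.testing.assert_allclose(rep1.confusion_percent,
                                   rep2.confusion_percent)

    def test_probability_validation(self):
        with pytest.raises(ValueError):
            FoldResult("S", np.array([[0.5, 0.6]]), np.array(["A"]),
                       np.array(["A"]), ["A", "N"])
        with pytest.raises(ValueError):
            FoldResult("S", np.array([[-0.1, 1.1]]), np.array(["A"]),
                       np.array(["A"]), ["A", "N"])


class TestRunLoocv:
    def test_balanced_test_folds_and_above_chance_on_separable_data(self):
        ds = _dataset(4, per_class=3, seed=7)
        folds = run_loocv(ds, hyperparams={"n_estimators": 20,
                                           "colsample_bytree": 1.0}, seed=0)
        assert len(folds) == 4
        for f in folds:
            counts = {c: int(np.sum(f.y_true == c)) for c in set(f.y_true)}
            assert len(set(counts.values())) == 1  # balanced after undersampling
        rep = evaluate(folds)
        assert rep.macro_roc_auc > 0.9
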