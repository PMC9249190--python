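"""Feature tables, splits, model search, metrics and LOSO protocol."""

import numpy as np
import pandas as pd
import pytest

from cortimuscle.coherence import CouplingVector
from cortimuscle.features import (FeatureTableError, build_table, evaluate,
                                  leave_one_subject_out,
                                  metrics_from_confusion, model_search,
                                  predictor_columns, split_train_test,
                                  train_and_evaluate)


def make_vectors(n_subjects=2, n_tasks=2, n_trials=3, n_emg=4, p=53,
                 method="CD", band="total", seed=0):
    rng = np.random.default_rng(seed)
    out = []
    for s in range(n_subjects):
        for t in range(1, n_tasks + 1):
            for tr in range(n_trials):
                for m in range(n_emg):
                    label = m < 2 if t <= 2 else m >= 2
                    out.append(CouplingVector(
                        values=np.abs(rng.standard_normal(p)), method=method,
                        band=band, subject_id=s, task_id=t, trial_id=tr,
                        emg_channel=m, label=bool(label)))
    return out


class TestBuildTable:
    def test_binary_shape(self):
        vecs = make_vectors()
        table = build_table(vecs, mode="binary")
        assert len(table) == len(vecs)
        assert len(predictor_columns(table)) == 53
        assert set(table["label"]) == {0, 1}

    def test_multitask_concatenates_emg_channels(self):
        vecs = make_vectors(n_tasks=4)
        table = build_table(vecs, mode="multitask")
        assert len(table) == 2 * 4 * 3           # subjects x tasks x trials
        assert len(predictor_columns(table)) == 4 * 53
        assert set(table["label"]) == {1, 2, 3, 4}

    def test_single_vector_single_row(self):
        (v,) = make_vectors(1, 1, 1, 1)
        table = build_table([v], mode="binary")
        assert len(table) == 1
        assert table.loc[0, "label"] == int(v.label)

    def test_mixed_methods_rejected(self):
        vecs = make_vectors(method="CD") + make_vectors(method="msCoh")
        with pytest.raises(FeatureTableError):
            build_table(vecs)


class TestSplit:
    def test_sizes_and_balance(self):
        table = build_table(make_vectors(4, 4, 5), mode="binary")
        train, test = split_train_test(table, test_frac=0.2, seed=0)
        assert len(train) == 256 and len(test) == 64
        assert abs(test["label"].mean() - 0.5) <= 1 / len(test)
        # disjoint rows
        key = ["subject", "task", "trial", "emg_channel"]
        overlap = pd.merge(train[key], test[key])
        assert overlap.empty

    def test_seed_reproducibility(self):
        table = build_table(make_vectors(), mode="binary")
        a1, b1 = split_train_test(table, seed=5)
        a2, b2 = split_train_test(table, seed=5)
        pd.testing.assert_frame_equal(a1, a2)
        pd.testing.assert_frame_equal(b1, b2)

    def test_zero_test_frac_rejected(self):
        table = build_table(make_vectors(), mode="binary")
        with pytest.raises(ValueError):
            split_train_test(table, test_frac=0.0)


def two_gaussians(n=200, sep=6.0, seed=0, p=4):
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((n, p))
    y = (np.arange(n) % 2).astype(int)
    X[y == 1, 0] += sep
    return X, y


class TestModelSearch:
    def test_separable_data_low_cv_error(self):
        X, y = two_gaussians(sep=6.0)
        res = model_search(X, y, budget=7, seed=0)
        assert res.cv_error <= 0.05
        assert len(res.cv_loss_trace) == 7

    def test_permuted_labels_near_chance(self):
        rng = np.random.default_rng(1)
        X, y = two_gaussians(n=300, sep=6.0, seed=1)
        y = rng.permutation(y)
        res = model_search(X, y, budget=7, seed=1)
        acc = 1.0 - res.cv_error
        assert 0.35 < acc < 0.65

    def test_deterministic_given_seed(self):
        X, y = two_gaussians(n=120, sep=2.0, seed=2)
        r1 = model_search(X, y, budget=14, seed=9)
        r2 = model_search(X, y, budget=14, seed=9)
        assert r1.family == r2.family and r1.cv_error == r2.cv_error
        assert r1.params == r2.params

    def test_budget_below_families_rejected(self):
        X, y = two_gaussians()
        with pytest.raises(ValueError):
            model_search(X, y, budget=3)


class TestEvaluate:
    class _Fixed:
        def __init__(self, pred):
            self.pred = np.asarray(pred)

        def predict(self, X):
            return self.pred[: len(X)]

    def test_perfect_classifier(self):
        y = np.array([1] * 10 + [0] * 10)
        ev = evaluate(self._Fixed(y), np.zeros((20, 2)), y)
        assert (ev.sensitivity, ev.specificity, ev.accuracy) == (100, 100, 100)

    def test_hand_computed_counts(self):
        # TP=5, FN=5, TN=8, FP=2 -> 50% / 80% / 65%
        y = np.array([1] * 10 + [0] * 10)
        pred = np.array([1] * 5 + [0] * 5 + [0] * 8 + [1] * 2)
        ev = evaluate(self._Fixed(pred), np.zeros((20, 2)), y)
        assert (ev.tp, ev.fn, ev.tn, ev.fp) == (5, 5, 8, 2)
        assert ev.sensitivity == pytest.approx(50.0)
        assert ev.specificity == pytest.approx(80.0)
        assert ev.accuracy == pytest.approx(65.0)

    def test_all_positive_on_balanced(self):
        y = np.array([1] * 8 + [0] * 8)
        ev = evaluate(self._Fixed(np.ones(16, dtype=int)), np.zeros((16, 2)), y)
        assert ev.sensitivity == 100.0
        assert ev.specificity == 0.0
        assert ev.accuracy == 50.0

    def test_empty_test_set_rejected(self):
        with pytest.raises(ValueError):
            evaluate(self._Fixed([1]), np.zeros((0, 2)), np.array([]))

    def test_metric_identities_fuzz(self, rng):
        """Formulas reproduce exactly from random confusion counts."""
        for _ in range(300):
            tp, tn, fp, fn = rng.integers(1, 100, size=4)
            sens, spec, acc = metrics_from_confusion(tp, tn, fp, fn)
            assert sens == pytest.approx(100.0 * tp / (tp + fn))
            assert spec == pytest.approx(100.0 * tn / (tn + fp))
            assert acc == pytest.approx(100.0 * (tn + tp) / (tn + fp + tp + fn))

    def test_multiclass_macro_metrics(self):
        y = np.array([1, 1, 2, 2, 3, 3, 4, 4])
        ev = evaluate(self._Fixed(y), np.zeros((8, 2)), y)
        assert ev.confusion.shape == (4, 4)
        assert ev.accuracy == 100.0
        assert ev.sensitivity == 100.0


class TestLoso:
    def _table(self, n_subjects=4, sep=6.0):
        rows = []
        rng = np.random.default_rng(0)
        for s in range(n_subjects):
            X, y = two_gaussians(n=60, sep=sep, seed=s)
            for i in range(len(y)):
                rows.append({"subject": s, "task": 1, "trial": i,
                             "emg_channel": i % 4, "method": "CD",
                             "band": "total", "label": int(y[i]),
                             "f0": X[i, 0], "f1": X[i, 1], "f2": X[i, 2],
                             "f3": X[i, 3]})
        return pd.DataFrame(rows)

    def test_one_result_per_subject(self):
        res = leave_one_subject_out(self._table(4), budget=7, seed=0)
        assert sorted(res) == [0, 1, 2, 3]

    def test_separable_subjects_near_perfect(self):
        res = leave_one_subject_out(self._table(2), budget=7, seed=0)
        assert all(r.accuracy >= 95.0 for r in res.values())

    def test_duplicate_subject_ids_rejected(self):
        t = self._table(2)
        pairs = [(0, t[t.subject == 0]), (0, t[t.subject == 1])]
        with pytest.raises(ValueError):
            leave_one_subject_out(pairs)

    def test_single_subject_rejected(self):
        with pytest.raises(ValueError):
            leave_one_subject_out(self._table(1))


class TestTrainAndEvaluate:
    def test_end_to_end_on_separable_table(self):
        table = build_table(make_vectors(3, 2, 4), mode="binary")
        cols = predictor_columns(table)
        # plant a strong signal in one predictor
        table.loc[table.label == 1, cols[0]] += 8.0
        train, test = split_train_test(table, seed=0)
        ev = train_and_evaluate(train, test, budget=7, seed=0)
        assert ev.accuracy >= 90.0
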