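"""Confusion counts, the five metrics, CV/holdout protocols and AUC."""

import itertools

import numpy as np
import pytest

from gliomatex import FeatureTable, confusion, holdout_split, kfold_cv, metrics, roc_auc
from gliomatex.evaluate import ConfusionCounts
from gliomatex.fixtures_io import ParameterError

from _oracles import auc_pairs_oracle


class TestConfusion:
    def test_perfect_prediction_no_errors(self):
        y = ["a", "b", "a", "c"]
        counts = confusion(y, y, ["a", "b", "c"])
        for c in counts.values():
            assert c.FP == 0 and c.FN == 0

    def test_hand_tally(self):
        # class A: 4 TP, 1 FP, 0 FN, 5 TN in 10 rows
        y_true = ["A", "A", "A", "A", "B", "B", "B", "C", "C", "C"]
        y_pred = ["A", "A", "A", "A", "A", "B", "B", "C", "C", "C"]
        c = confusion(y_true, y_pred, ["A", "B", "C"])["A"]
        assert (c.TP, c.FP, c.FN, c.TN) == (4, 1, 0, 5)

    def test_counts_sum_to_n_per_class(self, rng):
        labs = ["x", "y", "z"]
        y_true = rng.choice(labs, 30)
        y_pred = rng.choice(labs, 30)
        for c in confusion(y_true, y_pred, labs).values():
            assert c.n == 30

    def test_label_outside_codebook_rejected(self):
        with pytest.raises(ParameterError):
            confusion(["a"], ["q"], ["a", "b"])


class TestMetrics:
    def test_hand_evaluated_counts(self):
        rep = metrics({"A": ConfusionCounts(TP=4, TN=5, FP=1, FN=0)})
        m = rep.per_class["A"]
        assert m["ACC"] == pytest.approx(0.9)
        assert m["TPR"] == pytest.approx(1.0)
        assert m["PPV"] == pytest.approx(0.8)
        assert m["SPC"] == pytest.approx(5 / 6)
        assert m["DSC"] == pytest.approx(8 / 9)

    def test_perfect_predictions_all_ones(self):
        rep = metrics({"A": ConfusionCounts(3, 7, 0, 0)})
        assert all(v == 1.0 for v in rep.per_class["A"].values())

    def test_dsc_is_harmonic_mean_of_ppv_tpr(self, rng):
        for _ in range(1000):
            tp, tn, fp, fn = rng.integers(0, 20, 4)
            if tp == 0:
                continue
            m = metrics({"c": ConfusionCounts(int(tp), int(tn),
                                              int(fp), int(fn))}).per_class["c"]
            hm = 2 * m["PPV"] * m["TPR"] / (m["PPV"] + m["TPR"])
            assert m["DSC"] == pytest.approx(hm, abs=1e-12)

    def test_exhaustive_small_tuples_match_formulas(self):
        for tp, tn, fp, fn in itertools.product(range(5), repeat=4):
            if tp + tn + fp + fn == 0:
                continue
            import warnings
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                m = metrics({"c": ConfusionCounts(tp, tn, fp, fn)}).per_class["c"]
            assert m["ACC"] == pytest.approx((tp + tn) / (tp + tn + fp + fn))
            if tp + fn:
                assert m["TPR"] == pytest.approx(tp / (tp + fn))
            if tp + fp:
                assert m["PPV"] == pytest.approx(tp / (tp + fp))
            if tn + fp:
                assert m["SPC"] == pytest.approx(tn / (tn + fp))
            if 2 * tp + fp + fn:
                assert m["DSC"] == pytest.approx(2 * tp / (2 * tp + fp + fn))

    def test_zero_denominator_defined_as_zero_with_warning(self):
        with pytest.warns(UserWarning):
            m = metrics({"c": ConfusionCounts(0, 4, 0, 0)}).per_class["c"]
        assert m["TPR"] == 0.0


class _NearestCentroid:
    """Tiny deterministic stand-in pipeline for protocol tests."""

    def __init__(self, table):
        y = np.asarray(table.labels)
        self.classes = sorted(set(y))
        self.centroids = {c: table.values[y == c].mean(axis=0)
                          for c in self.classes}

    def predict(self, X):
        d = np.stack([np.linalg.norm(X - self.centroids[c], axis=1)
                      for c in self.classes])
        return np.asarray(self.classes)[np.argmin(d, axis=0)]


def _toy_table(rng, n_per_class=10, groups=None):
    X = np.vstack([rng.normal(i * 3, 0.5, (n_per_class, 4)) for i in range(3)])
    y = sum([[c] * n_per_class for c in ("a", "b", "c")], [])
    return FeatureTable(X, [f"f.c{i}" for i in range(4)], labels=y,
                        groups=groups)


class TestKfold:
    def test_folds_partition_rows(self, rng):
        t = _toy_table(rng)
        rep = kfold_cv(_NearestCentroid, t, k=5, seed=0)
        folds = np.array(rep.fold_assignments)
        assert len(folds) == t.n_rows
        assert set(folds) == set(range(5))

    def test_leave_one_out_boundary(self, rng):
        t = _toy_table(rng, n_per_class=4)
        rep = kfold_cv(_NearestCentroid, t, k=4, seed=0)
        assert len(rep.per_fold) == 4

    def test_same_seed_reproduces_folds_and_metrics(self, rng):
        t = _toy_table(rng)
        r1 = kfold_cv(_NearestCentroid, t, k=5, seed=3)
        r2 = kfold_cv(_NearestCentroid, t, k=5, seed=3)
        assert r1.fold_assignments == r2.fold_assignments
        assert r1.macro == r2.macro

    def test_groups_never_straddle_folds(self, rng):
        groups = [f"g{i // 2}" for i in range(30)]  # pairs share a parent
        t = _toy_table(rng, groups=groups)
        rep = kfold_cv(_NearestCentroid, t, k=5, seed=0)
        folds = np.array(rep.fold_assignments)
        for g in set(groups):
            sel = np.array(groups) == g
            assert len(set(folds[sel])) == 1

    def test_k_exceeding_class_count_rejected(self, rng):
        with pytest.raises(ParameterError):
            kfold_cv(_NearestCentroid, _toy_table(rng, n_per_class=4), k=10)


class TestHoldout:
    def test_balanced_stratified_counts(self, rng):
        t = _toy_table(rng, n_per_class=10)
        train, test = holdout_split(t, test_fraction=0.40, seed=0)
        assert test.n_rows == 12  # 40% of 30, 4 per class
        for c in "abc":
            assert sum(1 for l in test.labels if l == c) == 4

    def test_groups_stay_together(self, rng):
        groups = [f"g{i // 3}" for i in range(30)]
        t = _toy_table(rng, groups=groups)
        train, test = holdout_split(t, test_fraction=0.40, seed=0)
        assert set(train.groups).isdisjoint(set(test.groups))

    def test_same_seed_same_split(self, rng):
        t = _toy_table(rng)
        a = holdout_split(t, seed=9)
        b = holdout_split(t, seed=9)
        np.testing.assert_array_equal(a[1].values, b[1].values)


class TestRocAuc:
    def test_perfect_separation(self):
        scores = np.array([[0.9], [0.8], [0.2], [0.1]])
        auc = roc_auc(scores, ["p", "p", "n", "n"], ["p"])
        assert auc["p"] == 1.0

    def test_uninformative_scores_half(self):
        scores = np.full((6, 1), 0.5)
        auc = roc_auc(scores, ["p", "n", "p", "n", "p", "n"], ["p"])
        assert auc["p"] == 0.5

    def test_four_score_pair_counting(self):
        # negatives {0.1, 0.35}, positives {0.4, 0.8}: all 4 pairs concordant
        scores = np.array([[0.1], [0.4], [0.35], [0.8]])
        y = ["n", "p", "n", "p"]
        assert roc_auc(scores, y, ["p"])["p"] == pytest.approx(
            auc_pairs_oracle([0.1, 0.4, 0.35, 0.8], [0, 1, 0, 1]))
        assert roc_auc(scores, y, ["p"])["p"] == 1.0

    def test_matches_pair_counting_on_all_small_sets(self, rng):
        for _ in range(50):
            n = int(rng.integers(4, 9))
            s = rng.choice([0.1, 0.3, 0.5, 0.7, 0.9], n)
            y01 = rng.integers(0, 2, n)
            if y01.min() == y01.max():
                continue
            y = np.where(y01 == 1, "p", "n")
            got = roc_auc(s[:, None], y, ["p"])["p"]
            assert got == pytest.approx(auc_pairs_oracle(s.tolist(),
                                                         y01.tolist()))

    def test_single_class_rejected(self):
        with pytest.raises(ParameterError):
            roc_auc(np.array([[0.5], [0.6]]), ["p", "p"], ["p"])
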