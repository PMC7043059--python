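"""Kappa, cross-validation metrics, heat-map correlations, clustering, network, chi-squared."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.spatial.distance import pdist
from scipy.stats import chi2_contingency
from sklearn.metrics import cohen_kappa_score

import chemopercept as cp
from chemopercept.association import (ConfusionMatrix, chi2_2x2,
                                      feature_class_correlation)
from chemopercept.datatypes import ValidationError


class TestKappa:
    @pytest.mark.parametrize("diag", [[5], [3, 7], [1, 2, 3, 4], [10] * 12])
    def test_diagonal_only_matrix_gives_exactly_one(self, diag):
        cm = np.diag(diag)
        assert cp.cohen_kappa(cm) == 1.0

    def test_chance_level_agreement_gives_zero(self):
        assert cp.cohen_kappa(np.array([[25, 25], [25, 25]])) == pytest.approx(0.0)

    def test_hand_computed_three_class_value(self):
        cm = np.array([[10, 2, 0], [1, 12, 1], [0, 3, 11]])
        assert cp.cohen_kappa(cm) == pytest.approx(391 / 531, abs=1e-12)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_random_matrices_agree_with_sklearn(self, seed):
        rng = np.random.default_rng(seed)
        cm = rng.integers(0, 20, size=(5, 5))
        if cm.sum() == 0 or np.isclose(
                (cm.sum(1) / cm.sum()) @ (cm.sum(0) / cm.sum()), 1.0):
            return
        y_true = np.repeat(np.arange(5), cm.sum(axis=1))
        y_pred = np.concatenate([np.repeat(np.arange(5), cm[i]) for i in range(5)])
        assert cp.cohen_kappa(cm) == pytest.approx(
            cohen_kappa_score(y_true, y_pred), abs=1e-12)

    def test_kappa_one_iff_no_off_diagonal(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            cm = rng.integers(0, 10, size=(4, 4))
            if cm.sum() == 0:
                continue
            off = cm.sum() - np.trace(cm)
            if off == 0 and np.count_nonzero(np.diag(cm)) >= 2:
                assert cp.cohen_kappa(cm) == 1.0
            elif off > 0:
                assert cp.cohen_kappa(cm) < 1.0

    def test_invariant_under_class_permutation(self):
        rng = np.random.default_rng(2)
        cm = rng.integers(0, 15, size=(4, 4))
        perm = rng.permutation(4)
        assert cp.cohen_kappa(cm) == pytest.approx(
            cp.cohen_kappa(cm[np.ix_(perm, perm)]), abs=1e-12)

    def test_empty_matrix_rejected(self):
        with pytest.raises(ValidationError):
            cp.cohen_kappa(np.zeros((3, 3)))


class _Memorizer:
    """Learner factory that memorizes its training data (1-NN on exact rows)."""

    def __init__(self, train):
        self.X = train.table.values
        self.y = train.y

    def predict_indices(self, X):
        out = np.empty(X.shape[0], dtype=int)
        for i, row in enumerate(X):
            d = np.abs(self.X - row).sum(axis=1)
            out[i] = self.y[np.argmin(d)]
        return out


class _Majority:
    def __init__(self, train):
        self.cls = int(np.bincount(train.y).argmax())

    def predict_indices(self, X):
        return np.full(X.shape[0], self.cls, dtype=int)


class TestCrossValidate:
    def test_perfect_learner_on_separable_data(self, two_class_separable):
        folds = cp.make_folds(two_class_separable, k=4, seed=0)
        cv = cp.cross_validate(two_class_separable, folds, _Memorizer)
        assert cv.accuracy_mean == pytest.approx(1.0)
        assert cv.accuracy_sd == pytest.approx(0.0)
        assert cv.kappa_mean == pytest.approx(1.0)

    def test_majority_dummy_matches_class_prior(self, strong_signal):
        ds, _ = strong_signal
        folds = cp.make_folds(ds, k=4, seed=0)
        cv = cp.cross_validate(ds, folds, _Majority)
        prior = max(ds.class_counts().values()) / ds.n_molecules
        assert cv.accuracy_mean == pytest.approx(prior, abs=0.05)

    def test_pooled_confusion_consistent_with_fold_accuracies(self, strong_signal):
        ds, _ = strong_signal
        folds = cp.make_folds(ds, k=4, seed=1)
        cv = cp.cross_validate(
            ds, folds, lambda tr: cp.fit_forest(tr, cp.ForestConfig(20, seed=0)))
        sizes = folds.fold_sizes()
        weighted = np.average(cv.fold_accuracies, weights=sizes)
        assert cv.confusion.accuracy() == pytest.approx(weighted)
        assert cv.confusion.total == ds.n_molecules


class TestFeatureClassCorrelation:
    def test_indicator_feature_correlates_perfectly(self):
        labels = ["a"] * 10 + ["b"] * 20
        values = np.array([[1.0]] * 10 + [[0.0]] * 20)
        table = cp.DescriptorTable([f"M{i}" for i in range(30)], ["ind"],
                                   values, np.zeros((30, 1), bool))
        ds = cp.LabeledDataset(table, labels, ["a", "b"])
        M = feature_class_correlation(ds, ["ind"])
        assert M.loc["ind", "a"] == pytest.approx(1.0)
        # two classes partitioning the data: the complement correlates at -1
        assert M.loc["ind", "b"] == pytest.approx(-1.0)

    def test_noise_feature_near_zero(self, no_signal):
        ds, _ = no_signal
        j = int(np.argmax(ds.table.values.std(axis=0) > 0))
        M = feature_class_correlation(ds, [ds.table.feature_names[j]])
        n = ds.n_molecules
        assert (M.abs().to_numpy() < 3 / np.sqrt(n)).all()

    def test_constant_feature_warns_and_returns_zero(self, two_class_separable):
        values = np.c_[two_class_separable.table.values, np.ones(40)]
        table = cp.DescriptorTable(two_class_separable.table.molecule_ids,
                                   ["x", "const"], values,
                                   np.zeros((40, 2), bool))
        ds = cp.LabeledDataset(table, two_class_separable.labels, ["high", "low"])
        with pytest.warns(UserWarning, match="constant"):
            M = feature_class_correlation(ds, ["const"])
        assert (M.to_numpy() == 0).all()


class TestClustering:
    def test_identical_rows_merge_first(self):
        M = np.array([[1.0, 2.0], [5.0, 9.0], [1.0, 2.0]])
        res = cp.hierarchical_cluster(M)
        assert res.row_linkage[0, 2] == 0.0  # first merge at distance 0
        assert sorted(res.row_linkage[0, :2]) == [0, 2]

    def test_block_matrix_groups_separated_in_leaf_order(self):
        M = np.vstack([np.tile([10.0, 0.0, 0.0], (3, 1)) + np.eye(3),
                       np.tile([0.0, 0.0, 10.0], (3, 1)) - np.eye(3)])
        res = cp.hierarchical_cluster(M)
        pos = {r: i for i, r in enumerate(res.row_order)}
        groups = sorted(pos[r] for r in range(3)), sorted(pos[r] for r in range(3, 6))
        assert groups[0] == [0, 1, 2] or groups[0] == [3, 4, 5]

    def test_linkage_distances_are_euclidean(self):
        M = np.array([[0.0, 0.0], [3.0, 4.0]])
        res = cp.hierarchical_cluster(M)
        assert res.row_linkage[0, 2] == pytest.approx(5.0)
        assert res.row_linkage[0, 2] == pytest.approx(pdist(M)[0])

    def test_single_row_is_trivial(self):
        res = cp.hierarchical_cluster(np.array([[1.0, 2.0, 3.0]]))
        assert res.row_order == [0] and res.row_linkage is None


class TestZscore:
    def test_basic_and_idempotent(self):
        np.testing.assert_allclose(cp.zscore([1.0, 2.0, 3.0]), [-1.0, 0.0, 1.0])
        z = cp.zscore([4.0, 1.0, 7.0, 2.0])
        np.testing.assert_allclose(cp.zscore(z), z, atol=1e-12)
        assert z.mean() == pytest.approx(0.0, abs=1e-12)
        assert z.std(ddof=1) == pytest.approx(1.0)

    def test_constant_vector_rejected(self):
        with pytest.raises(ValidationError):
            cp.zscore([2.0, 2.0, 2.0])


class TestCrossModalNetwork:
    def _frames(self, seed=0, n=60):
        rng = np.random.default_rng(seed)
        ids = [f"M{i}" for i in range(n)]
        shared = rng.standard_normal(n)
        A = pd.DataFrame({"c1": rng.standard_normal(n), "both": shared}, index=ids)
        B = pd.DataFrame({"o1": rng.standard_normal(n), "both": shared}, index=ids)
        return A, B

    def test_identical_feature_is_shared_with_unit_self_correlation(self):
        A, B = self._frames()
        net = cp.cross_modal_network(A, B)
        assert net.shared_features() == ["both"]
        assert net.graph.has_edge("both", "both")
        assert net.graph["both"]["both"]["r"] == pytest.approx(1.0)

    def test_impossible_threshold_gives_no_edges(self):
        A, B = self._frames()
        net = cp.cross_modal_network(A, B, threshold=1.01)
        assert net.graph.number_of_edges() == 0

    def test_edge_set_monotone_in_threshold(self):
        A, B = self._frames(seed=3)
        prev = None
        for t in [0.0, 0.1, 0.3, 0.6, 1.0]:
            edges = {frozenset((u, v)) for u, v, _ in
                     cp.cross_modal_network(A, B, threshold=t).edges}
            if prev is not None:
                assert edges <= prev
            prev = edges

    def test_too_few_shared_molecules_rejected(self):
        A, B = self._frames(n=2)
        with pytest.raises(ValidationError):
            cp.cross_modal_network(A, B)


class TestChiSquare:
    def test_closed_form_2x2(self):
        # n(ad-bc)^2 / ((a+b)(c+d)(a+c)(b+d))
        res = chi2_2x2(np.array([[10, 0], [0, 10]]))
        assert res.statistic == pytest.approx(20.0, abs=1e-9)
        res = chi2_2x2(np.array([[12, 5], [3, 10]]))
        assert res.statistic == pytest.approx(6.65158371040724, abs=1e-9)

    def test_exact_independence_gives_zero(self):
        res = chi2_2x2(np.array([[10, 20], [20, 40]]))
        assert res.statistic == pytest.approx(0.0, abs=1e-12)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_agrees_with_scipy_both_conventions(self, seed):
        rng = np.random.default_rng(seed)
        t = rng.integers(1, 30, size=(2, 2))
        for yates in (False, True):
            ours = chi2_2x2(t, yates=yates)
            ref = chi2_contingency(t, correction=yates)
            assert ours.statistic == pytest.approx(ref.statistic, abs=1e-9)
            assert ours.p_value == pytest.approx(ref.pvalue, abs=1e-9)

    def test_empty_margin_rejected(self):
        with pytest.raises(ValidationError):
            chi2_2x2(np.array([[0, 0], [5, 5]]))

    def test_dichotomization_rule(self):
        colors = ["white", "colorless", "Red", "amber", "gray", "white"]
        odors = ["odorless", "Odorless", "spicy", "sweet", "odorless", "fruity"]
        res = cp.dichotomize_chi2(colors, odors)
        # pale = white/colorless only (amber and gray count as "other")
        np.testing.assert_array_equal(res.table, [[2, 1], [1, 2]])

    def test_mismatched_lengths_rejected(self):
        with pytest.raises(ValidationError):
            cp.dichotomize_chi2(["white"], [])


def test_confusion_matrix_from_predictions_roundtrip():
    y_true = np.array([0, 0, 1, 2, 2, 2])
    y_pred = np.array([0, 1, 1, 2, 2, 0])
    cm = ConfusionMatrix.from_predictions(y_true, y_pred, ["a", "b", "c"])
    assert cm.total == 6
    assert cm.counts[0, 1] == 1 and cm.counts[2, 0] == 1
    assert cm.accuracy() == pytest.approx(4 / 6)
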