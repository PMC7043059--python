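"""GA wrapper selection, run consensus, and |acc2 - acc1| permutation ranking."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import chemopercept as cp
from chemopercept.datatypes import ValidationError
from chemopercept.selection import (GAConfig, _fitness_function, consensus,
                                    ga_select, permutation_rank)


def _toy_dataset(p=10, n=60, informative=2, seed=0):
    spec = cp.SyntheticSpec(n_molecules=n, n_features=p, n_classes=2,
                            informative_per_class=informative // 2 or 1,
                            effect_size=4.0, seed=seed)
    return cp.generate_dataset(spec)


def _two_key_dataset(p=10, per_class=20, seed=0):
    """3 classes keyed by two features: f0 high in class a, f1 high in class b,
    neither high in class c — both keys are required for 3-way separation."""
    rng = np.random.default_rng(seed)
    n = 3 * per_class
    values = rng.standard_normal((n, p))
    values[:per_class, 0] += 5.0
    values[per_class:2 * per_class, 1] += 5.0
    table = cp.DescriptorTable([f"M{i}" for i in range(n)],
                               [f"f{j}" for j in range(p)], values,
                               np.zeros((n, p), bool))
    return cp.LabeledDataset(table, ["a"] * per_class + ["b"] * per_class
                             + ["c"] * per_class, ["a", "b", "c"])


class TestGASelect:
    def test_finds_informative_features_confirmed_by_exhaustive_oracle(self):
        ds = _two_key_dataset(p=10, seed=5)
        cfg = GAConfig(population_size=16, generations=10, fitness_folds=2,
                       fitness_trees=5, guided_init=False, seed=0)
        # oracle: exhaustive search over all 2^10 masks under the same fitness
        fitness, _ = _fitness_function(ds, cfg)
        best_mask, best_fit = None, -np.inf
        for bits in itertools.product([False, True], repeat=10):
            mask = np.array(bits)
            if not mask.any():
                continue
            f = fitness(mask)
            if f > best_fit:
                best_fit, best_mask = f, mask
        assert best_mask[0] and best_mask[1]  # optimum uses both key features
        hits = 0
        for seed in range(20):
            res = ga_select(ds, GAConfig(**{**cfg.__dict__, "seed": seed}))
            hits += bool(res.best_mask[0] and res.best_mask[1])
        assert hits >= 18

    def test_all_informative_toy_reaches_exhaustive_optimum(self):
        # p=4, every feature informative: the GA must land on the global
        # optimum of the fitness landscape enumerated over all 2^4 masks
        spec = cp.SyntheticSpec(n_molecules=80, n_features=4, n_classes=4,
                                informative_per_class=1, effect_size=4.0, seed=1)
        ds, _ = cp.generate_dataset(spec)
        cfg = GAConfig(population_size=10, generations=6, fitness_folds=2,
                       fitness_trees=10, guided_init=False, seed=3)
        fitness, _ = _fitness_function(ds, cfg)
        best_fit = max(fitness(np.array(b)) for b in
                       itertools.product([False, True], repeat=4)
                       if any(b))
        res = ga_select(ds, cfg)
        assert res.best_fitness == pytest.approx(best_fit, abs=1e-12)

    def test_degenerate_single_individual_single_generation(self):
        ds, _ = _toy_dataset(seed=2)
        cfg = GAConfig(population_size=1, generations=1, fitness_folds=2,
                       fitness_trees=3, elitism=1, guided_init=False, seed=4)
        res = ga_select(ds, cfg)
        assert res.best_trace == [res.best_fitness]

    def test_best_fitness_nondecreasing_under_elitism(self):
        ds, _ = _toy_dataset(seed=3)
        res = ga_select(ds, GAConfig(population_size=10, generations=8,
                                     fitness_folds=2, fitness_trees=5,
                                     guided_init=False, seed=1))
        assert all(b >= a for a, b in zip(res.best_trace, res.best_trace[1:]))

    def test_determinism(self):
        ds, _ = _toy_dataset(seed=4)
        cfg = GAConfig(population_size=8, generations=4, fitness_folds=2,
                       fitness_trees=4, seed=9)
        a = ga_select(ds, cfg)
        b = ga_select(ds, cfg)
        np.testing.assert_array_equal(a.best_mask, b.best_mask)
        assert a.best_trace == b.best_trace


class TestConsensus:
    def test_always_selected_feature_at_full_threshold(self):
        masks = [np.array([True, False, i % 2 == 0]) for i in range(20)]
        sel = consensus(masks, min_count=20)
        assert sel.consensus_mask.tolist() == [True, False, False]

    def test_zero_threshold_selects_everything(self):
        sel = consensus([np.array([False, False])], min_count=0)
        assert sel.consensus_mask.all()

    def test_empty_run_list_rejected(self):
        with pytest.raises(ValidationError):
            consensus([], min_count=1)

    @given(st.integers(0, 12))
    @settings(max_examples=13, deadline=None)
    def test_consensus_monotone_in_min_count(self, t):
        rng = np.random.default_rng(42)
        masks = [rng.random(15) < 0.5 for _ in range(12)]
        lo = consensus(masks, min_count=t).consensus_mask
        hi = consensus(masks, min_count=min(t + 1, 12)).consensus_mask
        assert (~hi | lo).all()  # raising the threshold never adds features


class TestPermutationRank:
    @pytest.fixture(scope="class")
    def fitted(self):
        spec = cp.SyntheticSpec(n_molecules=200, n_features=30, n_classes=3,
                                informative_per_class=2, effect_size=3.0, seed=6)
        ds, truth = cp.generate_dataset(spec)
        train = ds.subset_rows(np.arange(0, 140))
        val = ds.subset_rows(np.arange(140, 200))
        model = cp.fit_forest(train, cp.ForestConfig(n_trees=40, seed=0))
        return train, val, model, truth

    def test_acc1_equals_plain_validation_accuracy(self, fitted):
        _, val, model, _ = fitted
        res = permutation_rank(model, val, repetitions=2, seed=0)
        assert res.acc1 == pytest.approx(model.accuracy(val))

    def test_unused_feature_has_zero_indicator(self, fitted):
        train, val, model, _ = fitted
        used = set()
        for t in model.trees:
            f = t.tree_.feature
            used |= set(f[f >= 0].tolist())
        unused = [j for j in range(30) if j not in used]
        if unused:  # permuting a never-split feature cannot change predictions
            res = permutation_rank(model, val, repetitions=2, seed=1)
            assert all(res.indicators[j] == 0 for j in unused)

    def test_planted_features_occupy_top_ranks_majority(self, fitted):
        train, val, _, truth = fitted
        planted = set(truth.all_informative())
        hits = 0
        for seed in range(5):
            model = cp.fit_forest(train, cp.ForestConfig(n_trees=40, seed=seed))
            res = permutation_rank(model, val, repetitions=5, seed=seed)
            top = set(res.rank_order[: len(planted)].tolist())
            hits += len(top & planted) >= len(planted) - 1
        assert hits >= 3

    def test_refit_mode_absorbs_forest_randomness(self, fitted):
        train, val, _, _ = fitted

        def refit(seed):
            return cp.fit_forest(train, cp.ForestConfig(n_trees=20, seed=seed))

        res = permutation_rank(None, val, repetitions=3, seed=2, refit=refit)
        assert res.repetitions == 3
        assert (res.indicators >= 0).all()

    def test_empty_validation_rejected(self, fitted):
        train, val, model, _ = fitted
        empty = val.subset_rows(np.array([], dtype=int))
        with pytest.raises(ValidationError):
            permutation_rank(model, empty, repetitions=1, seed=0)

    def test_duplicated_feature_splits_importance(self):
        # the copies together retain at least half the original indicator
        spec = cp.SyntheticSpec(n_molecules=160, n_features=8, n_classes=2,
                                informative_per_class=1, effect_size=3.0, seed=7)
        ds, truth = cp.generate_dataset(spec)
        j = truth.all_informative()[0]
        wins = 0
        for seed in range(5):
            train = ds.subset_rows(np.arange(0, 110))
            val = ds.subset_rows(np.arange(110, 160))
            model = cp.fit_forest(train, cp.ForestConfig(n_trees=30, seed=seed))
            base = permutation_rank(model, val, repetitions=5, seed=seed)

            dup_values = np.c_[ds.table.values, ds.table.values[:, j]]
            table = cp.DescriptorTable(
                ds.table.molecule_ids, ds.table.feature_names + ["dup"],
                dup_values, np.zeros_like(dup_values, dtype=bool))
            dup_ds = cp.LabeledDataset(table, ds.labels, ds.vocabulary)
            d_train = dup_ds.subset_rows(np.arange(0, 110))
            d_val = dup_ds.subset_rows(np.arange(110, 160))
            d_model = cp.fit_forest(d_train, cp.ForestConfig(n_trees=30, seed=seed))
            dup = permutation_rank(d_model, d_val, repetitions=5, seed=seed)
            wins += (dup.indicators[j] + dup.indicators[-1]
                     >= 0.5 * base.indicators[j])
        assert wins >= 3

    def test_indicator_separates_signal_from_chance(self, no_signal,
                                                    strong_signal):
        """Ranking shows class signal where planted and stays flat where not.

        On a finite fixed validation split the |acc2 - acc1| indicator of
        a pure-noise feature is positive by chance (the forest overfits
        noise), so the comparison is within each dataset: on planted
        data each class's strongest planted feature must beat the
        background's 90th percentile; on pure-noise data no feature may
        look decisively important.
        """
        def indicators(ds):
            train = ds.subset_rows(np.arange(0, 80))
            val = ds.subset_rows(np.arange(80, 120))
            model = cp.fit_forest(train, cp.ForestConfig(n_trees=40, seed=0))
            return permutation_rank(model, val, repetitions=10, seed=3).indicators

        ds_s, truth = strong_signal
        signal_ind = indicators(ds_s)
        planted = set(truth.all_informative())
        background = [signal_ind[j] for j in range(50) if j not in planted]
        cutoff = np.percentile(background, 90)
        for cols in truth.informative_features.values():
            assert max(signal_ind[j] for j in cols) > cutoff

        noise_ind = indicators(no_signal[0])
        assert noise_ind.max() < 0.1
        # and the average chance-level indicator is small in absolute terms
        assert noise_ind.mean() < 0.05
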