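"""Random-forest classification with out-of-bag permutation importance.

The forest follows the Breiman recipe used throughout this pipeline:
``n_trees`` (nTree, default 100) decision trees, each grown on a
bootstrap sample of the molecules with ``m_try`` candidate descriptors
per split (default floor(sqrt(p)); 72 for the 5,270-descriptor Dragon
tables), prediction by majority vote.  Individual trees are scikit-learn
``DecisionTreeClassifier`` instances; bagging, voting and the per-tree
out-of-bag records needed for permutation importance are handled here,
because importance is defined on each tree's own out-of-bag molecules.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from sklearn.tree import DecisionTreeClassifier

from .datatypes import LabeledDataset, ValidationError


def default_mtry(p: int) -> int:
    """Number of candidate descriptors per split: floor(sqrt(p)).

    ``default_mtry(5270) == 72``, the convention used for the full
    Dragon descriptor tables.
    """
    if p < 1:
        raise ValidationError("p must be >= 1")
    return int(math.isqrt(p))


@dataclass
class ForestConfig:
    """Hyperparameters of the forest (nTree=100, mTry=floor(sqrt(p)))."""

    n_trees: int = 100
    m_try: int | None = None  # None -> floor(sqrt(p)) at fit time
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trees < 1:
            raise ValidationError("n_trees must be >= 1")
        if self.m_try is not None and self.m_try < 1:
            raise ValidationError("m_try must be >= 1")


@dataclass
class ForestModel:
    """A fitted forest plus the bootstrap records its trees were grown on."""

    config: ForestConfig
    vocabulary: list[str]
    feature_names: list[str]
    trees: list[DecisionTreeClassifier]
    bootstrap_indices: list[np.ndarray]
    n_train: int

    @property
    def n_classes(self) -> int:
        return len(self.vocabulary)

    def _votes(self, X: np.ndarray) -> np.ndarray:
        """Per-sample vote counts over the vocabulary; rows sum to n_trees."""
        votes = np.zeros((X.shape[0], self.n_classes), dtype=int)
        rows = np.arange(X.shape[0])
        for tree in self.trees:
            pred = tree.predict(X).astype(int)
            votes[rows, pred] += 1
        return votes

    def predict_indices(self, X: np.ndarray) -> np.ndarray:
        """Majority vote; ties broken toward the lowest vocabulary index."""
        return np.argmax(self._votes(np.asarray(X, dtype=float)), axis=1)

    def predict(self, X: np.ndarray) -> list[str]:
        return [self.vocabulary[i] for i in self.predict_indices(X)]

    def accuracy(self, dataset: LabeledDataset) -> float:
        pred = self.predict_indices(dataset.table.values)
        return float(np.mean(pred == dataset.y))


def fit_forest(train: LabeledDataset, config: ForestConfig | None = None) -> ForestModel:
    """Grow a bootstrap forest on a labeled dataset.

    Deterministic under ``config.seed``.  Raises if the training data
    holds fewer than two classes.
    """
    config = config or ForestConfig()
    X = train.table.values
    y = train.y
    if np.unique(y).size < 2:
        raise ValidationError("training data must contain at least 2 classes")
    n, p = X.shape
    m_try = config.m_try if config.m_try is not None else default_mtry(p)
    if m_try > p:
        raise ValidationError(f"m_try={m_try} exceeds feature count p={p}")
    rng = np.random.default_rng(config.seed)
    trees: list[DecisionTreeClassifier] = []
    boots: list[np.ndarray] = []
    for _ in range(config.n_trees):
        idx = rng.integers(0, n, size=n)
        tree = DecisionTreeClassifier(
            max_features=m_try,
            random_state=int(rng.integers(2**31)),
        )
        # classes present in the bootstrap may be a subset; map to global ints
        tree.fit(X[idx], y[idx])
        trees.append(tree)
        boots.append(idx)
    return ForestModel(
        config=ForestConfig(config.n_trees, m_try, config.seed),
        vocabulary=list(train.vocabulary),
        feature_names=list(train.table.feature_names),
        trees=trees,
        bootstrap_indices=boots,
        n_train=n,
    )


def oob_error(model: ForestModel, train: LabeledDataset) -> float:
    """Out-of-bag misclassification rate of the whole forest.

    Each molecule is predicted by majority vote over the trees that did
    not see it in their bootstrap sample; molecules in every bootstrap
    are skipped.
    """
    X, y = train.table.values, train.y
    n = X.shape[0]
    votes = np.zeros((n, model.n_classes), dtype=int)
    for tree, idx in zip(model.trees, model.bootstrap_indices):
        oob = np.setdiff1d(np.arange(n), idx, assume_unique=False)
        if oob.size == 0:
            continue
        pred = tree.predict(X[oob]).astype(int)
        votes[oob, pred] += 1
    covered = votes.sum(axis=1) > 0
    if not covered.any():
        raise ValidationError("no out-of-bag molecules; add trees")
    pred = np.argmax(votes[covered], axis=1)
    return float(np.mean(pred != y[covered]))


def oob_importance(model: ForestModel, train: LabeledDataset, seed: int = 0) -> np.ndarray:
    """Out-of-bag permutation importance per descriptor.

    For each tree and each descriptor used by that tree: permute the
    descriptor's values across the tree's out-of-bag molecules, and
    record the increase in the tree's OOB error.  The importance of a
    descriptor is the raw mean of this increase over all trees (trees
    that never split on it contribute exactly 0, so a descriptor unused
    by every tree scores exactly 0).
    """
    if not model.bootstrap_indices:
        raise ValidationError("model lacks bootstrap records")
    X, y = train.table.values, train.y
    n, p = X.shape
    rng = np.random.default_rng(seed)
    increases = np.zeros(p)
    for tree, idx in zip(model.trees, model.bootstrap_indices):
        oob = np.setdiff1d(np.arange(n), idx)
        if oob.size == 0:
            continue
        Xo, yo = X[oob], y[oob]
        base_err = np.mean(tree.predict(Xo).astype(int) != yo)
        used = np.unique(tree.tree_.feature)
        used = used[used >= 0]
        for j in used:
            perm = rng.permutation(oob.size)
            Xp = Xo.copy()
            Xp[:, j] = Xo[perm, j]
            err = np.mean(tree.predict(Xp).astype(int) != yo)
            increases[j] += err - base_err
    return increases / len(model.trees)


def save_forest(model: ForestModel, path) -> None:
    """Persist a fitted forest (config, vocabulary, trees, bootstraps)."""
    import joblib

    joblib.dump({"format": "chemopercept-forest", "version": 1,
                 "model": model}, path)


def load_forest(path) -> ForestModel:
    import joblib

    blob = joblib.load(path)
    if blob.get("format") != "chemopercept-forest":
        raise ValidationError(f"{path} is not a saved forest archive")
    return blob["model"]


def needed_features(importance: np.ndarray) -> np.ndarray:
    """Boolean mask of descriptors "needed" for classification.

    Negative permutation importances are clamped to 0 first; a
    descriptor is needed iff its clamped importance is strictly
    positive.
    """
    imp = np.clip(np.asarray(importance, dtype=float), 0.0, None)
    return imp > 0.0
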