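"""Core in-memory containers for descriptor tables, labels and CV folds.

A descriptor table is a dense molecules x descriptors matrix of real
numbers (Dragon-style output) together with an explicit missing-value
mask: entries flagged missing hold ``nan`` in ``values`` until they are
imputed.  Labels are a 12-way (by default) categorical vector over a
fixed ordered vocabulary.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np


class ValidationError(ValueError):
    """Raised when an input container or spec violates its invariants."""


@dataclass
class DescriptorTable:
    """Molecules x descriptors matrix with a missing-value mask.

    Parameters
    ----------
    molecule_ids : sequence of str
        Unique molecule identifiers (PubChem CID strings in real data).
    feature_names : sequence of str
        Unique descriptor names, one per column.
    values : (n, p) float array
        Descriptor values; entries flagged in ``missing_mask`` are nan.
    missing_mask : (n, p) bool array
        True where a value is missing.
    """

    molecule_ids: list[str]
    feature_names: list[str]
    values: np.ndarray
    missing_mask: np.ndarray

    def __post_init__(self) -> None:
        self.molecule_ids = [str(m) for m in self.molecule_ids]
        self.feature_names = [str(f) for f in self.feature_names]
        self.values = np.asarray(self.values, dtype=float)
        self.missing_mask = np.asarray(self.missing_mask, dtype=bool)
        n, p = self.values.shape
        if self.missing_mask.shape != (n, p):
            raise ValidationError(
                f"missing_mask shape {self.missing_mask.shape} != values shape {(n, p)}"
            )
        if len(self.molecule_ids) != n:
            raise ValidationError("molecule_ids length does not match values rows")
        if len(self.feature_names) != p:
            raise ValidationError("feature_names length does not match values columns")
        if len(set(self.molecule_ids)) != n:
            raise ValidationError("duplicate molecule ids")
        if len(set(self.feature_names)) != p:
            raise ValidationError("duplicate feature names")

    @property
    def n_molecules(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def copy(self) -> "DescriptorTable":
        return DescriptorTable(
            list(self.molecule_ids),
            list(self.feature_names),
            self.values.copy(),
            self.missing_mask.copy(),
        )

    def subset_rows(self, idx: np.ndarray) -> "DescriptorTable":
        idx = np.asarray(idx)
        return DescriptorTable(
            [self.molecule_ids[i] for i in idx],
            list(self.feature_names),
            self.values[idx],
            self.missing_mask[idx],
        )

    def subset_features(self, names: Sequence[str]) -> "DescriptorTable":
        pos = {f: j for j, f in enumerate(self.feature_names)}
        try:
            cols = np.array([pos[f] for f in names], dtype=int)
        except KeyError as exc:  # pragma: no cover - message path
            raise ValidationError(f"unknown feature {exc.args[0]!r}") from None
        return DescriptorTable(
            list(self.molecule_ids), [self.feature_names[c] for c in cols],
            self.values[:, cols], self.missing_mask[:, cols],
        )


@dataclass
class LabeledDataset:
    """A descriptor table joined to a categorical label vector."""

    table: DescriptorTable
    labels: list[str]
    vocabulary: list[str]

    def __post_init__(self) -> None:
        self.labels = [str(l) for l in self.labels]
        self.vocabulary = [str(v) for v in self.vocabulary]
        if len(self.labels) != self.table.n_molecules:
            raise ValidationError("labels length != number of molecules")
        unknown = set(self.labels) - set(self.vocabulary)
        if unknown:
            raise ValidationError(f"labels outside vocabulary: {sorted(unknown)}")
        if len(set(self.vocabulary)) != len(self.vocabulary):
            raise ValidationError("duplicate labels in vocabulary")

    @property
    def n_molecules(self) -> int:
        return self.table.n_molecules

    @property
    def y(self) -> np.ndarray:
        """Labels encoded as vocabulary indices."""
        lut = {v: i for i, v in enumerate(self.vocabulary)}
        return np.array([lut[l] for l in self.labels], dtype=int)

    def class_counts(self) -> dict[str, int]:
        return {v: self.labels.count(v) for v in self.vocabulary}

    def subset_rows(self, idx: np.ndarray) -> "LabeledDataset":
        idx = np.asarray(idx)
        return LabeledDataset(
            self.table.subset_rows(idx),
            [self.labels[i] for i in idx],
            list(self.vocabulary),
        )

    def subset_features(self, names: Sequence[str]) -> "LabeledDataset":
        return LabeledDataset(
            self.table.subset_features(names), list(self.labels), list(self.vocabulary)
        )

    def with_table(self, table: DescriptorTable) -> "LabeledDataset":
        return replace(self, table=table)


@dataclass
class FoldAssignment:
    """A k-fold partition of molecules, stored as a per-molecule fold index."""

    k: int
    fold_index: np.ndarray

    def __post_init__(self) -> None:
        self.fold_index = np.asarray(self.fold_index, dtype=int)
        if self.k < 2:
            raise ValidationError("k must be >= 2")
        if self.fold_index.min(initial=0) < 0 or self.fold_index.max(initial=0) >= self.k:
            raise ValidationError("fold indices outside [0, k)")
        counts = np.bincount(self.fold_index, minlength=self.k)
        if (counts == 0).any():
            raise ValidationError("every fold must be non-empty")

    def fold_sizes(self) -> np.ndarray:
        return np.bincount(self.fold_index, minlength=self.k)

    def split(self, fold: int) -> tuple[np.ndarray, np.ndarray]:
        """Return (train_idx, test_idx) for one fold."""
        test = np.flatnonzero(self.fold_index == fold)
        train = np.flatnonzero(self.fold_index != fold)
        return train, test
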