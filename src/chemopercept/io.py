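"""Descriptor-table I/O, preprocessing rules, and cross-validation folds.

Preprocessing follows the study conventions for Dragon descriptor tables:
molecules with more than 2,000 missing descriptor values are excluded,
remaining missing entries are imputed with 0, and model evaluation uses
stratified 4-fold cross-validation without oversampling.
"""

from __future__ import annotations

import csv
import io as _io
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datatypes import DescriptorTable, FoldAssignment, LabeledDataset, ValidationError

#: Tokens treated as missing when reading a descriptor CSV (case-insensitive).
MISSING_TOKENS = {"", "nan", "na"}

#: Default exclusion threshold: drop molecules with more missing entries than this.
DEFAULT_MAX_MISSING = 2000


class ParseError(ValueError):
    """Raised when a descriptor CSV violates the expected layout."""


def _is_missing(tok: str) -> bool:
    return tok.strip().lower() in MISSING_TOKENS


def read_descriptor_csv(path, label_column: str | None = "label"):
    """Read a descriptor table, optionally with a label column.

    The first row holds column names; the first column must be the
    molecule-ID column (``cid``).  Empty cells and the tokens ``NaN`` /
    ``na`` (any case) are flagged missing.  Returns a
    :class:`LabeledDataset` when ``label_column`` is given and present,
    otherwise a :class:`DescriptorTable`.
    """
    with open(path, "r", encoding="utf-8", newline="") as fh:
        rows = list(csv.reader(fh))
    if not rows:
        raise ParseError(f"{path}: empty file")
    header = rows[0]
    if len(header) < 2:
        raise ParseError(f"{path}: header must hold an ID column and descriptors")
    id_col = header[0]
    width = len(header)
    for i, row in enumerate(rows[1:], start=2):
        if len(row) != width:
            raise ParseError(f"{path}: row {i} has {len(row)} cells, expected {width}")

    has_label = label_column is not None and label_column in header[1:]
    label_pos = header.index(label_column) if has_label else None

    feature_cols = [
        j for j in range(1, width) if j != label_pos
    ]
    feature_names = [header[j] for j in feature_cols]
    if len(set(feature_names)) != len(feature_names):
        dupes = sorted({f for f in feature_names if feature_names.count(f) > 1})
        raise ParseError(f"{path}: duplicate descriptor columns {dupes}")

    ids: list[str] = []
    labels: list[str] = []
    n = len(rows) - 1
    values = np.empty((n, len(feature_cols)), dtype=float)
    mask = np.zeros((n, len(feature_cols)), dtype=bool)
    for i, row in enumerate(rows[1:]):
        ids.append(row[0])
        if label_pos is not None:
            labels.append(row[label_pos])
        for k, j in enumerate(feature_cols):
            tok = row[j]
            if _is_missing(tok):
                values[i, k] = np.nan
                mask[i, k] = True
            else:
                try:
                    values[i, k] = float(tok)
                except ValueError:
                    raise ParseError(
                        f"{path}: row {i + 2}, column {header[j]!r}: "
                        f"cannot parse {tok!r} as a number"
                    ) from None
    if len(set(ids)) != len(ids):
        dupes = sorted({m for m in ids if ids.count(m) > 1})
        raise ParseError(f"{path}: duplicate molecule ids in {id_col!r}: {dupes[:5]}")

    table = DescriptorTable(ids, feature_names, values, mask)
    if label_pos is None:
        return table
    vocabulary = sorted(set(labels))
    return LabeledDataset(table, labels, vocabulary)


def write_descriptor_csv(path, data: LabeledDataset | DescriptorTable) -> None:
    """Write a table in the ``cid,label,<descriptors...>`` CSV dialect.

    Numbers are written with 17 significant digits so that reading the
    file back reproduces the table bit-for-bit; missing entries are
    written as ``NaN``.
    """
    if isinstance(data, LabeledDataset):
        table, labels = data.table, data.labels
    else:
        table, labels = data, None
    with open(path, "w", encoding="utf-8", newline="") as fh:
        w = csv.writer(fh)
        header = ["cid"] + (["label"] if labels is not None else []) + table.feature_names
        w.writerow(header)
        for i, cid in enumerate(table.molecule_ids):
            cells = [cid] + ([labels[i]] if labels is not None else [])
            for j in range(table.n_features):
                if table.missing_mask[i, j]:
                    cells.append("NaN")
                else:
                    cells.append(f"{table.values[i, j]:.17g}")
            w.writerow(cells)


@dataclass
class FilterReport:
    """Which molecules an exclusion rule removed and why."""

    removed_ids: list[str]
    removed_missing_counts: list[int]
    max_missing: int


def filter_high_missing(
    table: DescriptorTable, max_missing: int = DEFAULT_MAX_MISSING
) -> tuple[DescriptorTable, FilterReport]:
    """Drop molecules with strictly more than ``max_missing`` missing entries.

    A molecule with exactly ``max_missing`` missing values is retained.
    Survivor order is preserved.  Returns the filtered table and a
    removal report.
    """
    if max_missing < 0:
        raise ValidationError("max_missing must be >= 0")
    counts = table.missing_mask.sum(axis=1)
    keep = counts <= max_missing
    report = FilterReport(
        removed_ids=[m for m, k in zip(table.molecule_ids, keep) if not k],
        removed_missing_counts=[int(c) for c, k in zip(counts, keep) if not k],
        max_missing=max_missing,
    )
    return table.subset_rows(np.flatnonzero(keep)), report


def impute_zero(table: DescriptorTable) -> DescriptorTable:
    """Replace every missing entry with 0 and clear the missing mask."""
    out = table.copy()
    out.values[out.missing_mask] = 0.0
    out.missing_mask[:] = False
    return out


def mean_missing_count(table: DescriptorTable) -> float:
    """Mean number of missing entries per molecule (computed pre-imputation)."""
    if table.n_molecules == 0:
        raise ValidationError("empty table")
    return float(table.missing_mask.sum(axis=1).mean())


def filter_labeled(
    dataset: LabeledDataset, max_missing: int = DEFAULT_MAX_MISSING
) -> tuple[LabeledDataset, FilterReport]:
    """`filter_high_missing` lifted to a labeled dataset."""
    counts = dataset.table.missing_mask.sum(axis=1)
    keep = np.flatnonzero(counts <= max_missing)
    report = FilterReport(
        removed_ids=[dataset.table.molecule_ids[i]
                     for i in np.flatnonzero(counts > max_missing)],
        removed_missing_counts=[int(counts[i])
                                for i in np.flatnonzero(counts > max_missing)],
        max_missing=max_missing,
    )
    return dataset.subset_rows(keep), report


def make_folds(
    dataset: LabeledDataset, k: int = 4, seed: int = 0, stratified: bool = True
) -> FoldAssignment:
    """Partition molecules into k cross-validation folds.

    By default the partition is stratified: each class's molecules are
    spread across folds as evenly as the class size allows (a class with
    fewer than k members appears in only some folds), and overall fold
    sizes differ by at most one.  Deterministic under ``seed``.
    """
    n = dataset.n_molecules
    if k < 2:
        raise ValidationError("k must be >= 2")
    if k > n:
        raise ValidationError(f"k={k} exceeds number of molecules n={n}")
    rng = np.random.default_rng(seed)
    fold_index = np.full(n, -1, dtype=int)
    if not stratified:
        perm = rng.permutation(n)
        for pos, i in enumerate(perm):
            fold_index[i] = pos % k
        return FoldAssignment(k, fold_index)

    y = dataset.y
    fold_counts = np.zeros(k, dtype=int)
    # largest classes first so remainders land on the emptiest folds
    classes = sorted(np.unique(y), key=lambda c: (-(y == c).sum(), c))
    for c in classes:
        members = np.flatnonzero(y == c)
        rng.shuffle(members)
        # cycle folds ordered by current fill so per-class and overall
        # counts both stay within one of each other
        order = np.array(sorted(range(k), key=lambda f: (fold_counts[f], f)))
        for pos, i in enumerate(members):
            f = order[pos % k]
            fold_index[i] = f
            fold_counts[f] += 1
    return FoldAssignment(k, fold_index)


def write_folds_csv(path, dataset: LabeledDataset, folds: FoldAssignment) -> None:
    """Export a fold assignment as a two-column CSV (cid, fold)."""
    df = pd.DataFrame(
        {"cid": dataset.table.molecule_ids, "fold": folds.fold_index}
    )
    df.to_csv(path, index=False)
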