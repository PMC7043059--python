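"""Evaluation metrics, feature-class clustering, and the cross-modal analysis.

Holds Cohen's kappa and cross-validated evaluation (accuracy and kappa,
mean +/- SD over folds, pooled confusion matrix), the point-biserial
feature x class correlation matrix behind the clustered heat maps, and
the color-odor cross-modal analysis: z-scoring of key descriptors,
a Pearson correlation network thresholded at |r| >= 0.300552, and the
chi-squared test on the dichotomized (white/colorless vs other) x
(odorless vs other) 2x2 table.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import networkx as nx
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.stats import chi2 as chi2_dist

from .datatypes import FoldAssignment, LabeledDataset, ValidationError

#: Default |r| cutoff of the cross-modal Pearson network.
DEFAULT_EDGE_THRESHOLD = 0.300552

#: Color labels pooled into the "pale" category of the dichotomized test.
PALE_COLORS = frozenset({"white", "colorless"})


@dataclass
class ConfusionMatrix:
    """c x c counts; rows are true labels, columns predicted labels."""

    counts: np.ndarray
    vocabulary: list[str]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        c = len(self.vocabulary)
        if self.counts.shape != (c, c):
            raise ValidationError("counts must be square over the vocabulary")
        if (self.counts < 0).any():
            raise ValidationError("counts must be non-negative")

    @classmethod
    def from_predictions(cls, y_true: np.ndarray, y_pred: np.ndarray,
                         vocabulary: list[str]) -> "ConfusionMatrix":
        c = len(vocabulary)
        counts = np.zeros((c, c), dtype=int)
        np.add.at(counts, (np.asarray(y_true, int), np.asarray(y_pred, int)), 1)
        return cls(counts, list(vocabulary))

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def accuracy(self) -> float:
        return float(np.trace(self.counts) / self.total)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.vocabulary,
                            columns=self.vocabulary)


def cohen_kappa(cm: ConfusionMatrix | np.ndarray) -> float:
    """Chance-corrected agreement kappa = (p_o - p_e) / (1 - p_e).

    p_o is the observed agreement (trace / total) and p_e the expected
    agreement from the row and column margins.  A diagonal-only matrix
    gives exactly 1; when chance agreement is total (p_e = 1, a single
    occupied class) kappa is 1 for perfect agreement by convention.
    """
    counts = cm.counts if isinstance(cm, ConfusionMatrix) else np.asarray(cm, dtype=float)
    total = counts.sum()
    if total <= 0:
        raise ValidationError("empty confusion matrix")
    p_o = np.trace(counts) / total
    row = counts.sum(axis=1) / total
    col = counts.sum(axis=0) / total
    p_e = float(row @ col)
    if np.isclose(p_e, 1.0):
        return 1.0 if np.isclose(p_o, 1.0) else 0.0
    return float((p_o - p_e) / (1.0 - p_e))


@dataclass
class CVResult:
    """Per-fold accuracies and kappas, their mean +/- SD, pooled confusion."""

    fold_accuracies: list[float]
    fold_kappas: list[float]
    confusion: ConfusionMatrix
    skipped_folds: list[int] = field(default_factory=list)

    @property
    def accuracy_mean(self) -> float:
        return float(np.mean(self.fold_accuracies))

    @property
    def accuracy_sd(self) -> float:
        return float(np.std(self.fold_accuracies, ddof=1)) \
            if len(self.fold_accuracies) > 1 else 0.0

    @property
    def kappa_mean(self) -> float:
        return float(np.mean(self.fold_kappas))

    @property
    def kappa_sd(self) -> float:
        return float(np.std(self.fold_kappas, ddof=1)) \
            if len(self.fold_kappas) > 1 else 0.0


def cross_validate(dataset: LabeledDataset, folds: FoldAssignment, learner) -> CVResult:
    """Evaluate a learner fold by fold.

    ``learner`` is a factory: called with a training LabeledDataset it
    returns a fitted model exposing ``predict_indices``.  A fold whose
    training complement holds fewer than two classes is skipped with a
    warning.
    """
    c = len(dataset.vocabulary)
    pooled = np.zeros((c, c), dtype=int)
    accs: list[float] = []
    kappas: list[float] = []
    skipped: list[int] = []
    y = dataset.y
    for f in range(folds.k):
        tr, te = folds.split(f)
        if np.unique(y[tr]).size < 2:
            warnings.warn(f"fold {f} skipped: training data lacks class diversity")
            skipped.append(f)
            continue
        model = learner(dataset.subset_rows(tr))
        pred = np.asarray(model.predict_indices(dataset.table.values[te]), dtype=int)
        cm = ConfusionMatrix.from_predictions(y[te], pred, dataset.vocabulary)
        pooled += cm.counts
        accs.append(cm.accuracy())
        kappas.append(cohen_kappa(cm))
    if not accs:
        raise ValidationError("all folds skipped")
    return CVResult(accs, kappas, ConfusionMatrix(pooled, list(dataset.vocabulary)),
                    skipped)


def zscore(values: np.ndarray) -> np.ndarray:
    """Standardize to mean 0, SD 1 (sample SD, ddof=1)."""
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValidationError("need at least 2 values to z-score")
    sd = x.std(ddof=1)
    if sd == 0:
        raise ValidationError("zero standard deviation; cannot z-score")
    return (x - x.mean()) / sd


def feature_class_correlation(dataset: LabeledDataset,
                              features: list[str]) -> pd.DataFrame:
    """Point-biserial correlation of each feature with each class indicator.

    Entry (f, c) is the Pearson correlation between descriptor f and the
    one-hot indicator of class c.  Constant descriptors yield 0 (with a
    warning) rather than an error.
    """
    sub = dataset.subset_features(features)
    X = sub.table.values
    y = sub.y
    n = X.shape[0]
    out = np.zeros((len(features), len(dataset.vocabulary)))
    onehot = np.zeros((n, len(dataset.vocabulary)))
    onehot[np.arange(n), y] = 1.0
    oh_sd = onehot.std(axis=0)
    for i in range(len(features)):
        x = X[:, i]
        if x.std() == 0:
            warnings.warn(f"constant descriptor {features[i]!r}; correlation set to 0")
            continue
        xc = (x - x.mean()) / x.std()
        for c in range(len(dataset.vocabulary)):
            if oh_sd[c] == 0:
                continue
            out[i, c] = float(np.mean(xc * (onehot[:, c] - onehot[:, c].mean())) / oh_sd[c])
    return pd.DataFrame(out, index=list(features), columns=list(dataset.vocabulary))


@dataclass
class ClusterResult:
    """Leaf orders and merge trees of a two-way hierarchical clustering."""

    row_order: list[int]
    col_order: list[int]
    row_linkage: np.ndarray | None
    col_linkage: np.ndarray | None


def hierarchical_cluster(matrix: pd.DataFrame | np.ndarray) -> ClusterResult:
    """Agglomerative clustering of rows and columns (Euclidean, average linkage)."""
    M = matrix.values if isinstance(matrix, pd.DataFrame) else np.asarray(matrix, float)
    if not np.isfinite(M).all():
        raise ValidationError("matrix must be finite")

    def one_way(A: np.ndarray):
        if A.shape[0] < 2:
            return list(range(A.shape[0])), None
        Z = linkage(A, method="average", metric="euclidean")
        return [int(i) for i in leaves_list(Z)], Z

    row_order, row_Z = one_way(M)
    col_order, col_Z = one_way(M.T)
    return ClusterResult(row_order, col_order, row_Z, col_Z)


@dataclass
class CrossModalNetwork:
    """Feature nodes from two modalities, Pearson-weighted edges above a cutoff."""

    graph: nx.Graph
    threshold: float

    @property
    def edges(self) -> list[tuple[str, str, float]]:
        return [(u, v, d["r"]) for u, v, d in self.graph.edges(data=True)]

    def shared_features(self) -> list[str]:
        return sorted(n for n, d in self.graph.nodes(data=True)
                      if d["modality"] == "shared")

    def to_edge_frame(self) -> pd.DataFrame:
        rows = [{"feature_a": u, "feature_b": v, "r": r} for u, v, r in self.edges]
        return pd.DataFrame(rows, columns=["feature_a", "feature_b", "r"])


def cross_modal_network(
    color_features: pd.DataFrame,
    odor_features: pd.DataFrame,
    shared_molecule_ids: list[str] | None = None,
    threshold: float = DEFAULT_EDGE_THRESHOLD,
) -> CrossModalNetwork:
    """Pearson network between color-key and odor-key descriptors.

    Both frames are indexed by molecule id (columns are descriptors) and
    are restricted to the shared molecules; descriptors are z-scored
    before correlating.  Every color-key x odor-key pair with
    |r| >= threshold becomes an edge; a descriptor present in both key
    sets is tagged ``shared`` (its self-pair correlates at 1 when the
    columns agree).
    """
    if shared_molecule_ids is None:
        shared_molecule_ids = [m for m in color_features.index
                               if m in set(odor_features.index)]
    if len(shared_molecule_ids) < 3:
        raise ValidationError("need at least 3 shared molecules")
    A = color_features.loc[shared_molecule_ids]
    B = odor_features.loc[shared_molecule_ids]
    shared = set(A.columns) & set(B.columns)
    g = nx.Graph(threshold=threshold)
    for f in A.columns:
        g.add_node(f, modality="shared" if f in shared else "color-key")
    for f in B.columns:
        if f not in g:
            g.add_node(f, modality="odor-key")
    za = {f: zscore(A[f].to_numpy()) for f in A.columns if A[f].std() > 0}
    zb = {f: zscore(B[f].to_numpy()) for f in B.columns if B[f].std() > 0}
    n = len(shared_molecule_ids)
    for fa, xa in za.items():
        for fb, xb in zb.items():
            if fa == fb:
                r = float(np.corrcoef(xa, xb)[0, 1])
            else:
                r = float((xa * xb).sum() / ((n - 1)))
            if abs(r) >= threshold:
                g.add_edge(fa, fb, r=r)
    return CrossModalNetwork(graph=g, threshold=threshold)


def plot_feature_class_heatmap(matrix: pd.DataFrame, path, cluster: bool = True):
    """Render a feature x class correlation heat map to PNG/SVG.

    Rows and columns are reordered by the Euclidean average-linkage
    clustering when ``cluster`` is set.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    import seaborn as sns

    M = matrix
    if cluster and min(M.shape) >= 2:
        res = hierarchical_cluster(M)
        M = M.iloc[res.row_order, res.col_order]
    fig, ax = plt.subplots(
        figsize=(max(4, 0.4 * M.shape[1] + 2), max(3, 0.25 * M.shape[0] + 1)))
    sns.heatmap(M, cmap="vlag", center=0.0, vmin=-1, vmax=1,
                cbar_kws={"label": "point-biserial r"}, ax=ax)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
    return path


@dataclass
class ChiSquareResult:
    """Pearson chi-squared on a 2x2 table (1 degree of freedom)."""

    table: np.ndarray
    statistic: float
    p_value: float
    dof: int = 1
    yates: bool = False


def chi2_2x2(table: np.ndarray, yates: bool = False) -> ChiSquareResult:
    """Pearson chi-squared for a 2x2 contingency table via expected counts."""
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValidationError("need a non-negative 2x2 table")
    n = t.sum()
    row = t.sum(axis=1)
    col = t.sum(axis=0)
    if (row == 0).any() or (col == 0).any():
        raise ValidationError("chi-squared undefined with an empty margin")
    expected = np.outer(row, col) / n
    diff = np.abs(t - expected)
    if yates:
        diff = np.maximum(diff - 0.5, 0.0)
    stat = float((diff**2 / expected).sum())
    return ChiSquareResult(
        table=t.astype(int), statistic=stat,
        p_value=float(chi2_dist.sf(stat, 1)), yates=yates,
    )


def dichotomize_chi2(
    colors: list[str], odors: list[str], yates: bool = False
) -> ChiSquareResult:
    """Chi-squared association between pale colors and odorlessness.

    Colors collapse to {white/colorless, other} and odors to
    {odorless, other}; the resulting 2x2 table is tested with Pearson's
    chi-squared (1 dof, no continuity correction unless ``yates``).
    """
    if len(colors) != len(odors):
        raise ValidationError("color and odor label vectors differ in length")
    if not colors:
        raise ValidationError("empty label vectors")
    pale = np.array([c.strip().lower() in PALE_COLORS for c in colors])
    odorless = np.array([o.strip().lower() == "odorless" for o in odors])
    table = np.array([
        [int(np.sum(pale & odorless)), int(np.sum(pale & ~odorless))],
        [int(np.sum(~pale & odorless)), int(np.sum(~pale & ~odorless))],
    ])
    return chi2_2x2(table, yates=yates)
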