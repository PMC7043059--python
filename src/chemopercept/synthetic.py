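"""Synthetic descriptor tables with planted class-coding features.

The generator emulates the statistical shape of Dragon descriptor
tables used for 12-way color/odor classification: a few thousand
continuous or integer-valued descriptors on wildly heterogeneous
scales, a sparse subset of class-informative columns, imbalanced class
sizes, and uniformly random missing entries.  Every dataset carries a
ground-truth record of which features were planted for which class, so
downstream feature selection and ranking can be scored against truth.

Background descriptors are drawn from a heavy-tailed scale mixture
(per-feature log-normal scales) rather than a standard normal, which
exercises the z-scoring and [0,1] input-scaling paths the way real
descriptor blocks do.  An informative feature for class ``c`` has its
mean shifted by ``effect_size`` noise standard deviations for the
molecules of class ``c`` only.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from .datatypes import DescriptorTable, LabeledDataset, ValidationError

#: Class sizes of the color dataset (1,267 molecules, 12 colors).
COLOR_PROFILE: dict[str, int] = {
    "colorless": 560, "white": 301, "yellow": 257, "orange": 31, "green": 24,
    "brown": 20, "black": 17, "red": 16, "amber": 15, "purple": 11,
    "blue": 9, "gray": 6,
}

#: Class sizes of the odor dataset (598 molecules, 12 odors).
ODOR_PROFILE: dict[str, int] = {
    "odorless": 162, "other": 127, "spicy": 54, "mild": 38, "ammonia": 37,
    "aromatic": 36, "sweet": 30, "fruity": 29, "characteristic": 27,
    "flower": 19, "unpleasant": 23, "pleasant": 16,
}

#: Fraction of background descriptors rounded to integers (count-like blocks).
_INTEGER_FRACTION = 0.3


@dataclass
class SyntheticSpec:
    """Parameters of a planted-structure descriptor dataset.

    ``effect_size`` is the mean shift of an informative feature inside
    its class, in units of that feature's noise SD; ``nan_rate`` is the
    uniform (MCAR) missingness probability; ``shared_feature_count``
    features code a class in *both* modalities of a paired dataset.
    """

    n_molecules: int
    n_features: int
    n_classes: int = 12
    class_sizes: list[int] | None = None
    informative_per_class: int = 5
    effect_size: float = 3.0
    nan_rate: float = 0.0
    shared_feature_count: int = 0
    seed: int = 0
    class_names: list[str] | None = None

    def __post_init__(self) -> None:
        if self.class_sizes is None:
            base = self.n_molecules // self.n_classes
            rem = self.n_molecules - base * self.n_classes
            self.class_sizes = [base + (1 if i < rem else 0)
                                for i in range(self.n_classes)]
        if self.class_names is None:
            self.class_names = [f"class{i:02d}" for i in range(self.n_classes)]
        self.validate()

    def validate(self) -> None:
        if self.n_molecules < 1 or self.n_features < 1 or self.n_classes < 1:
            raise ValidationError("all counts must be >= 1")
        if len(self.class_sizes) != self.n_classes:
            raise ValidationError("class_sizes length != n_classes")
        if any(s < 1 for s in self.class_sizes):
            raise ValidationError("every class must have >= 1 molecule")
        if sum(self.class_sizes) != self.n_molecules:
            raise ValidationError(
                f"class_sizes sums to {sum(self.class_sizes)}, "
                f"expected n_molecules={self.n_molecules}"
            )
        if not 0.0 <= self.nan_rate <= 1.0:
            raise ValidationError("nan_rate must lie in [0, 1]")
        if self.informative_per_class < 0 or self.shared_feature_count < 0:
            raise ValidationError("counts must be non-negative")
        if self.informative_per_class * self.n_classes > self.n_features:
            raise ValidationError("too many informative features for n_features")
        if self.shared_feature_count > self.informative_per_class * self.n_classes:
            raise ValidationError(
                "shared_feature_count exceeds total informative features"
            )
        if len(self.class_names) != self.n_classes:
            raise ValidationError("class_names length != n_classes")


def color_like_spec(n_features: int = 500, **kw) -> SyntheticSpec:
    """A spec replicating the color dataset's class imbalance."""
    names = list(COLOR_PROFILE)
    sizes = [COLOR_PROFILE[c] for c in names]
    kw.setdefault("seed", 0)
    return SyntheticSpec(
        n_molecules=sum(sizes), n_features=n_features, n_classes=len(names),
        class_sizes=sizes, class_names=names, **kw,
    )


def odor_like_spec(n_features: int = 500, **kw) -> SyntheticSpec:
    """A spec replicating the odor dataset's class imbalance."""
    names = list(ODOR_PROFILE)
    sizes = [ODOR_PROFILE[c] for c in names]
    kw.setdefault("seed", 0)
    return SyntheticSpec(
        n_molecules=sum(sizes), n_features=n_features, n_classes=len(names),
        class_sizes=sizes, class_names=names, **kw,
    )


@dataclass
class GroundTruth:
    """Planted structure of a synthetic dataset."""

    informative_features: dict[str, list[int]]  # class name -> column indices
    feature_scales: np.ndarray
    original_values: np.ndarray  # pre-missingness matrix
    spec: SyntheticSpec

    def all_informative(self) -> list[int]:
        out: list[int] = []
        for idx in self.informative_features.values():
            out.extend(idx)
        return sorted(set(out))

    def to_json(self) -> str:
        spec_d = asdict(self.spec)
        return json.dumps(
            {
                "spec": spec_d,
                "informative_features": self.informative_features,
                "seed": self.spec.seed,
            },
            indent=2,
        )


def _draw_background(rng: np.random.Generator, n: int, p: int):
    """Heavy-tailed background: per-feature log-normal scales and offsets."""
    scales = np.exp(rng.normal(0.0, 1.5, size=p))
    offsets = rng.normal(0.0, 1.0, size=p) * scales
    values = offsets + scales * rng.standard_normal((n, p))
    return values, scales


def _integerize(rng: np.random.Generator, values: np.ndarray,
                informative: np.ndarray) -> None:
    """Round a fraction of background columns to integers, in place."""
    p = values.shape[1]
    background = np.flatnonzero(~informative)
    n_int = int(round(_INTEGER_FRACTION * p))
    if n_int == 0 or background.size == 0:
        return
    cols = rng.choice(background, size=min(n_int, background.size), replace=False)
    values[:, cols] = np.round(values[:, cols])


def _plant(values: np.ndarray, scales: np.ndarray, y: np.ndarray,
           planted: dict[int, list[int]], effect_size: float) -> None:
    for c, cols in planted.items():
        rows = np.flatnonzero(y == c)
        for j in cols:
            values[rows, j] += effect_size * scales[j]


def generate_dataset(spec: SyntheticSpec) -> tuple[LabeledDataset, GroundTruth]:
    """Generate one labeled descriptor table with planted class signal.

    Pure function of ``spec`` (including its seed): repeated calls are
    bit-identical.  Informative features of distinct classes occupy
    disjoint columns.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n, p, k = spec.n_molecules, spec.n_features, spec.n_classes

    y = np.repeat(np.arange(k), spec.class_sizes)
    rng.shuffle(y)

    values, scales = _draw_background(rng, n, p)

    cols = rng.choice(p, size=spec.informative_per_class * k, replace=False)
    planted = {
        c: sorted(cols[c * spec.informative_per_class:(c + 1) * spec.informative_per_class].tolist())
        for c in range(k)
    }
    informative = np.zeros(p, dtype=bool)
    informative[cols] = True
    _integerize(rng, values, informative)
    _plant(values, scales, y, planted, spec.effect_size)

    molecule_ids = [f"SYN{100000 + i}" for i in range(n)]
    feature_names = [f"D{j:05d}" for j in range(p)]
    table = DescriptorTable(molecule_ids, feature_names, values,
                            np.zeros((n, p), dtype=bool))
    truth = GroundTruth(
        informative_features={spec.class_names[c]: planted[c] for c in range(k)},
        feature_scales=scales,
        original_values=values.copy(),
        spec=spec,
    )
    labels = [spec.class_names[c] for c in y]
    dataset = LabeledDataset(table, labels, list(spec.class_names))
    if spec.nan_rate > 0:
        dataset = dataset.with_table(
            inject_missing(table, spec.nan_rate, seed=int(rng.integers(2**31)))
        )
    return dataset, truth


def inject_missing(table: DescriptorTable, nan_rate: float, seed: int) -> DescriptorTable:
    """Mark entries missing uniformly at random at rate ``nan_rate``.

    Masked entries have their value replaced by nan; the pre-missingness
    values survive only in the generator's :class:`GroundTruth`.
    """
    if not 0.0 <= nan_rate <= 1.0:
        raise ValidationError("nan_rate must lie in [0, 1]")
    out = table.copy()
    if nan_rate == 0.0:
        return out
    rng = np.random.default_rng(seed)
    hit = rng.random(out.values.shape) < nan_rate
    out.missing_mask |= hit
    out.values[out.missing_mask] = np.nan
    return out


def generate_paired_dataset(
    spec: SyntheticSpec,
) -> tuple[LabeledDataset, LabeledDataset, GroundTruth, GroundTruth]:
    """Two labeled datasets over the same molecules (color-like and odor-like).

    Both label vectors partition the same molecules; each modality has
    its own planted informative columns, except that the first
    ``shared_feature_count`` informative columns are common to both
    modalities (they code a class in each), giving the cross-modal
    correlation network a known set of true shared nodes.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n, p, k = spec.n_molecules, spec.n_features, spec.n_classes
    m = spec.informative_per_class * k
    if spec.shared_feature_count > m:
        raise ValidationError("shared_feature_count exceeds informative total")
    if 2 * m - spec.shared_feature_count > p:
        raise ValidationError("not enough features for two informative sets")

    y_a = np.repeat(np.arange(k), spec.class_sizes)
    rng.shuffle(y_a)
    y_b = np.repeat(np.arange(k), spec.class_sizes)
    rng.shuffle(y_b)

    values, scales = _draw_background(rng, n, p)

    cols = rng.choice(p, size=2 * m - spec.shared_feature_count, replace=False)
    cols_a = cols[:m]
    # modality B reuses the first shared_feature_count columns of A
    cols_b = np.concatenate([cols_a[: spec.shared_feature_count], cols[m:]])
    planted_a = {c: sorted(cols_a[c * spec.informative_per_class:
                                  (c + 1) * spec.informative_per_class].tolist())
                 for c in range(k)}
    planted_b = {c: sorted(cols_b[c * spec.informative_per_class:
                                  (c + 1) * spec.informative_per_class].tolist())
                 for c in range(k)}
    informative = np.zeros(p, dtype=bool)
    informative[np.concatenate([cols_a, cols_b])] = True
    _integerize(rng, values, informative)
    _plant(values, scales, y_a, planted_a, spec.effect_size)
    _plant(values, scales, y_b, planted_b, spec.effect_size)

    molecule_ids = [f"SYN{100000 + i}" for i in range(n)]
    feature_names = [f"D{j:05d}" for j in range(p)]
    names_a = list(spec.class_names)
    names_b = [f"{c}_b" for c in spec.class_names]
    table = DescriptorTable(molecule_ids, feature_names, values,
                            np.zeros((n, p), dtype=bool))
    ds_a = LabeledDataset(table, [names_a[c] for c in y_a], names_a)
    ds_b = LabeledDataset(table.copy(), [names_b[c] for c in y_b], names_b)
    truth_a = GroundTruth({names_a[c]: planted_a[c] for c in range(k)},
                          scales, values.copy(), spec)
    truth_b = GroundTruth({names_b[c]: planted_b[c] for c in range(k)},
                          scales, values.copy(), spec)
    if spec.nan_rate > 0:
        s1, s2 = rng.integers(2**31, size=2)
        ds_a = ds_a.with_table(inject_missing(ds_a.table, spec.nan_rate, int(s1)))
        ds_b = ds_b.with_table(inject_missing(ds_b.table, spec.nan_rate, int(s2)))
    return ds_a, ds_b, truth_a, truth_b


def write_ground_truth(path, truth: GroundTruth) -> None:
    """Write the planted-feature record as a JSON sidecar."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(truth.to_json())
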