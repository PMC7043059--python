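"""Shared fixtures: small synthetic datasets with known planted structure."""

import numpy as np
import pytest

import chemopercept as cp


@pytest.fixture(scope="session")
def strong_signal():
    """n=120, p=50, 4 classes, 3 informative/class, effect size 3."""
    spec = cp.SyntheticSpec(
        n_molecules=120, n_features=50, n_classes=4,
        informative_per_class=3, effect_size=3.0, seed=1,
    )
    ds, truth = cp.generate_dataset(spec)
    return ds, truth


@pytest.fixture(scope="session")
def no_signal():
    """Same shape as strong_signal but with effect size 0 (pure noise)."""
    spec = cp.SyntheticSpec(
        n_molecules=120, n_features=50, n_classes=4,
        informative_per_class=3, effect_size=0.0, seed=1,
    )
    ds, truth = cp.generate_dataset(spec)
    return ds, truth


@pytest.fixture(scope="session")
def two_class_separable():
    """40 molecules, one feature that linearly separates two classes."""
    values = np.concatenate([np.linspace(0, 1, 20), np.linspace(5, 6, 20)])
    table = cp.DescriptorTable(
        [f"M{i}" for i in range(40)], ["x"], values[:, None],
        np.zeros((40, 1), dtype=bool),
    )
    labels = ["low"] * 20 + ["high"] * 20
    return cp.LabeledDataset(table, labels, ["high", "low"])
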