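"""End-to-end orchestration: read -> preprocess -> folds -> models -> report.

The pipeline mirrors the study workflow: descriptor tables are read (or
synthesized), molecules with more than 2,000 missing descriptors are
dropped, remaining missing entries are imputed with 0, stratified
4-fold cross-validation evaluates a random forest and/or a deep belief
network, optional feature selection restricts the descriptor set, and
association outputs (confusion matrix, kappa, heat-map matrix,
cross-modal network) are written alongside a machine-readable JSON
report.
"""

from __future__ import annotations

import hashlib
import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .datatypes import LabeledDataset, ValidationError
from . import io as cpio
from . import synthetic
from .association import (ConfusionMatrix, cross_validate, cohen_kappa,
                          feature_class_correlation, hierarchical_cluster,
                          plot_feature_class_heatmap)
from .dbn import fine_tune, pretrain_stack, scale_unit_interval
from .forest import ForestConfig, fit_forest, needed_features, oob_importance
from .selection import GAConfig, permutation_rank, run_ga_consensus

logger = logging.getLogger("chemopercept")

VALID_MODELS = ("forest", "dbn", "both")
VALID_FEATURE_SETS = ("all", "rf_selected", "ga_selected", "union")
VALID_TASKS = ("color", "odor", "crossmodal")


def derive_seed(master_seed: int, stream: str) -> int:
    """A named, reproducible seed stream derived from one master seed."""
    ss = np.random.SeedSequence(entropy=master_seed,
                                spawn_key=(zlib.crc32(stream.encode()),))
    return int(ss.generate_state(1)[0] % (2**31))


@dataclass
class PipelineConfig:
    """Configuration of a full run; exactly one input source."""

    task: str = "color"
    model: str = "forest"
    feature_set: str = "all"
    input_csv: str | None = None
    label_column: str = "label"
    synthetic_profile: str | None = None  # "color-like" | "odor-like" | "balanced"
    synthetic_kwargs: dict = field(default_factory=dict)
    k: int = 4
    seed: int = 0
    top_m: int = 24  # importance-selected feature count (24 color / 39 odor)
    n_trees: int = 100
    dbn_hidden: list[int] = field(default_factory=lambda: [500])
    dbn_epochs: tuple[int, int] = (20, 50)  # (pretrain, fine-tune)
    ga: dict = field(default_factory=dict)
    ga_runs: int = 20
    ga_min_count: int = 18
    output_dir: str = "chemopercept_out"

    def __post_init__(self) -> None:
        if self.model not in VALID_MODELS:
            raise ValidationError(f"model must be one of {VALID_MODELS}")
        if self.feature_set not in VALID_FEATURE_SETS:
            raise ValidationError(f"feature_set must be one of {VALID_FEATURE_SETS}")
        if self.task not in VALID_TASKS:
            raise ValidationError(f"task must be one of {VALID_TASKS}")
        if (self.input_csv is None) == (self.synthetic_profile is None):
            raise ValidationError(
                "exactly one of input_csv / synthetic_profile must be given"
            )

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        return cls(**d)

    def content_hash(self) -> str:
        blob = json.dumps(self.__dict__, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def load_dataset(config: PipelineConfig) -> LabeledDataset:
    if config.input_csv is not None:
        ds = cpio.read_descriptor_csv(config.input_csv, config.label_column)
        if not isinstance(ds, LabeledDataset):
            raise ValidationError("input CSV lacks the label column")
        return ds
    profile = config.synthetic_profile
    kw = dict(config.synthetic_kwargs)
    kw.setdefault("seed", derive_seed(config.seed, "synthetic"))
    if profile == "color-like":
        spec = synthetic.color_like_spec(**kw)
    elif profile == "odor-like":
        spec = synthetic.odor_like_spec(**kw)
    elif profile == "balanced":
        spec = synthetic.SyntheticSpec(**kw)
    else:
        raise ValidationError(f"unknown synthetic profile {profile!r}")
    ds, _truth = synthetic.generate_dataset(spec)
    return ds


def _forest_learner(config: PipelineConfig, stream: str):
    seed = derive_seed(config.seed, stream)

    def learner(train: LabeledDataset):
        return fit_forest(train, ForestConfig(n_trees=config.n_trees, seed=seed))

    return learner


def _dbn_learner(config: PipelineConfig, stream: str):
    seed = derive_seed(config.seed, stream)
    pre_epochs, ft_epochs = config.dbn_epochs

    class _DBNWrapper:
        def __init__(self, dbn, scaler):
            self.dbn, self.scaler = dbn, scaler

        def predict_indices(self, X):
            return self.dbn.predict_indices(self.scaler.transform(X))

    def learner(train: LabeledDataset):
        scaled, scaler = scale_unit_interval(train.table)
        layers = [train.table.n_features] + list(config.dbn_hidden)
        dbn = pretrain_stack(scaled.values, layers, epochs=pre_epochs, seed=seed)
        fine_tune(dbn, (scaled.values, train.y, list(train.vocabulary)),
                  epochs=ft_epochs, seed=seed)
        return _DBNWrapper(dbn, scaler)

    return learner


def _select_features(dataset: LabeledDataset, config: PipelineConfig):
    """Return (rf_top_m, ga_consensus) feature-name lists as requested."""
    rf_feats: list[str] = []
    ga_feats: list[str] = []
    if config.feature_set in ("rf_selected", "union"):
        model = fit_forest(dataset, ForestConfig(
            n_trees=config.n_trees, seed=derive_seed(config.seed, "rf-select")))
        imp = oob_importance(model, dataset,
                             seed=derive_seed(config.seed, "rf-select-perm"))
        order = np.argsort(-np.clip(imp, 0, None), kind="stable")
        rf_feats = [dataset.table.feature_names[j] for j in order[: config.top_m]]
    if config.feature_set in ("ga_selected", "union"):
        ga_cfg = GAConfig(**{"seed": derive_seed(config.seed, "ga"), **config.ga})
        sel, _runs = run_ga_consensus(
            dataset, ga_cfg, runs=config.ga_runs, min_count=config.ga_min_count,
            master_seed=derive_seed(config.seed, "ga-consensus"),
        )
        ga_feats = sel.consensus_features
    return rf_feats, ga_feats


def _restrict(dataset: LabeledDataset, config: PipelineConfig) -> tuple[LabeledDataset, dict]:
    if config.feature_set == "all":
        return dataset, {"feature_set": "all", "n_features": dataset.table.n_features}
    rf_feats, ga_feats = _select_features(dataset, config)
    if config.feature_set == "rf_selected":
        feats = rf_feats
    elif config.feature_set == "ga_selected":
        feats = ga_feats
    else:
        feats = sorted(set(rf_feats) | set(ga_feats))
    if not feats:
        raise ValidationError("feature selection returned an empty set")
    return dataset.subset_features(feats), {
        "feature_set": config.feature_set,
        "n_features": len(feats),
        "rf_selected": rf_feats,
        "ga_selected": ga_feats,
        "selected_features": feats,
    }


def run(config: PipelineConfig) -> dict:
    """Execute the configured pipeline; write and return the JSON report."""
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    logger.info("loading dataset")
    ds = load_dataset(config)
    ds, filt = cpio.filter_labeled(ds)
    mean_missing = cpio.mean_missing_count(ds.table)
    ds = ds.with_table(cpio.impute_zero(ds.table))
    folds = cpio.make_folds(ds, k=config.k, seed=derive_seed(config.seed, "folds"))
    ds_used, selection_info = _restrict(ds, config)

    report: dict = {
        "version": __version__,
        "config_hash": config.content_hash(),
        "task": config.task,
        "seed": config.seed,
        "n_molecules": ds.n_molecules,
        "n_excluded": len(filt.removed_ids),
        "mean_missing_per_molecule": mean_missing,
        "k": config.k,
        "selection": selection_info,
        "models": {},
    }

    learners = {}
    if config.model in ("forest", "both"):
        learners["forest"] = _forest_learner(config, "forest-cv")
    if config.model in ("dbn", "both"):
        learners["dbn"] = _dbn_learner(config, "dbn-cv")

    for name, learner in learners.items():
        logger.info("cross-validating %s", name)
        cv = cross_validate(ds_used, folds, learner)
        report["models"][name] = {
            "fold_accuracies": cv.fold_accuracies,
            "accuracy_mean": cv.accuracy_mean,
            "accuracy_sd": cv.accuracy_sd,
            "fold_kappas": cv.fold_kappas,
            "kappa_mean": cv.kappa_mean,
            "kappa_sd": cv.kappa_sd,
            "confusion_matrix": cv.confusion.counts.tolist(),
            "vocabulary": cv.confusion.vocabulary,
        }
        cv.confusion.to_frame().to_csv(outdir / f"confusion_{name}.csv")

    if config.feature_set != "all":
        M = feature_class_correlation(ds, selection_info["selected_features"])
        plot_feature_class_heatmap(M, outdir / "feature_class_heatmap.png")

    with open(outdir / "report.json", "w", encoding="utf-8") as fh:
        json.dump(report, fh, indent=2)
    return report


def compare_feature_sets(config: PipelineConfig) -> pd.DataFrame:
    """CV accuracy distributions for the four feature regimes.

    Regimes: all descriptors, the importance-selected top-m, the GA
    consensus set, and their union.  Returns a tidy frame (regime, fold,
    accuracy, n_features) with per-regime medians attached, and writes
    it under the configured output directory.
    """
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    ds = load_dataset(config)
    ds, _ = cpio.filter_labeled(ds)
    ds = ds.with_table(cpio.impute_zero(ds.table))
    folds = cpio.make_folds(ds, k=config.k, seed=derive_seed(config.seed, "folds"))
    # select once with both procedures, reuse across regimes
    rf_feats, ga_feats = _select_features(ds, _cfg_with(config, feature_set="union"))
    regimes = {
        "all": list(ds.table.feature_names),
        "rf_selected": rf_feats,
        "ga_selected": ga_feats,
        "union": sorted(set(rf_feats) | set(ga_feats)),
    }
    rows = []
    learner = _forest_learner(config, "forest-cv")
    for regime, feats in regimes.items():
        if not feats:
            logger.warning("regime %s is empty; skipped", regime)
            continue
        cv = cross_validate(ds.subset_features(feats), folds, learner)
        for f, acc in enumerate(cv.fold_accuracies):
            rows.append({"regime": regime, "fold": f, "accuracy": acc,
                         "n_features": len(feats)})
    df = pd.DataFrame(rows)
    medians = df.groupby("regime")["accuracy"].median().rename("median_accuracy")
    df = df.merge(medians, on="regime")
    df.to_csv(outdir / "feature_set_comparison.csv", index=False)
    return df


def _cfg_with(config: PipelineConfig, **kw) -> PipelineConfig:
    d = dict(config.__dict__)
    d.update(kw)
    return PipelineConfig(**d)
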