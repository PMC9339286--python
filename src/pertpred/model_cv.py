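"""TF-grouped cross-validation with gradient-boosted tree classifiers.

Folds are assigned at the TF level: all instances of a TF are held out
together, so a fold's model never sees binding or response data for its test
TFs. With the default 10 folds, each model trains on 90% of the TFs.
Training is single-threaded and seeded for bit-reproducible predictions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import xgboost as xgb

from .features import FeatureMatrix
from .labels import ResponseLabels

__all__ = [
    "Hyperparams",
    "FoldAssignment",
    "FoldModel",
    "TrainedModelSet",
    "make_tf_folds",
    "make_gene_folds",
    "train_fold",
    "cross_validate",
]


@dataclass(frozen=True)
class Hyperparams:
    """Gradient-boosted tree settings (binary logistic objective).

    Conventional settings for this problem size; all exposed in config.
    """

    n_rounds: int = 300
    max_depth: int = 6
    learning_rate: float = 0.05
    subsample: float = 0.8
    colsample_bytree: float = 0.8
    min_child_weight: float = 1.0
    scale_pos_weight: float = 1.0  # >1 enables positive-class reweighting
    seed: int = 0

    def to_xgb_params(self) -> dict:
        return {
            "objective": "binary:logistic",
            "max_depth": self.max_depth,
            "eta": self.learning_rate,
            "subsample": self.subsample,
            "colsample_bytree": self.colsample_bytree,
            "min_child_weight": self.min_child_weight,
            "scale_pos_weight": self.scale_pos_weight,
            "seed": self.seed,
            "nthread": 1,
            "tree_method": "hist",
            "verbosity": 0,
        }


QUICK_HYPERPARAMS = Hyperparams(n_rounds=100, max_depth=4)


@dataclass
class FoldAssignment:
    """Which fold holds out each group (TF by default)."""

    fold_count: int
    test_fold: dict[str, int]  # group id -> fold index
    seed: int
    by: str = "tf"  # {"tf", "gene"}

    def test_groups(self, fold: int) -> list[str]:
        return [g for g, f in self.test_fold.items() if f == fold]

    def train_groups(self, fold: int) -> list[str]:
        return [g for g, f in self.test_fold.items() if f != fold]


@dataclass
class FoldModel:
    booster: xgb.Booster
    feature_names: list[str]
    base_rate: float  # fraction of positive training instances
    fold: int


@dataclass
class TrainedModelSet:
    models: dict[int, FoldModel]
    assignment: FoldAssignment
    hyperparams: Hyperparams

    def model_for_tf(self, tf: str) -> FoldModel:
        return self.models[self.assignment.test_fold[tf]]


def _balanced_partition(items: list[str], fold_count: int, seed: int) -> dict[str, int]:
    if fold_count > len(items):
        raise ValueError(
            f"fold_count {fold_count} exceeds number of groups {len(items)}"
        )
    rng = np.random.default_rng(seed)
    shuffled = list(items)
    rng.shuffle(shuffled)
    assignment: dict[str, int] = {}
    for i, item in enumerate(shuffled):
        assignment[item] = i % fold_count
    return assignment


def make_tf_folds(tf_list: list[str], fold_count: int = 10, seed: int = 0
                  ) -> FoldAssignment:
    """Random balanced partition of TFs into test folds (sizes differ by <=1)."""
    return FoldAssignment(
        fold_count=fold_count,
        test_fold=_balanced_partition(list(tf_list), fold_count, seed),
        seed=seed,
        by="tf",
    )


def make_gene_folds(gene_list: list[str], fold_count: int = 10, seed: int = 0
                    ) -> FoldAssignment:
    """Gene-wise fold assignment (optional cross-validation variant)."""
    return FoldAssignment(
        fold_count=fold_count,
        test_fold=_balanced_partition(list(gene_list), fold_count, seed),
        seed=seed,
        by="gene",
    )


def _split_masks(matrix: FeatureMatrix, assignment: FoldAssignment, fold: int
                 ) -> tuple[np.ndarray, np.ndarray]:
    level = assignment.by
    groups = matrix.values.index.get_level_values(level)
    test_set = set(assignment.test_groups(fold))
    test_mask = np.asarray(groups.isin(test_set))
    return ~test_mask, test_mask


def train_fold(
    matrix: FeatureMatrix,
    labels: ResponseLabels,
    fold: int,
    assignment: FoldAssignment,
    hyperparams: Hyperparams | None = None,
) -> FoldModel:
    """Train the model for one fold on all instances of the non-test groups."""
    hp = hyperparams or Hyperparams()
    train_mask, _ = _split_masks(matrix, assignment, fold)
    X = matrix.values.loc[train_mask]
    y = labels.responsive.loc[X.index].to_numpy()
    if y.sum() == 0:
        raise ValueError(f"fold {fold}: training set has zero positive instances")
    dtrain = xgb.DMatrix(
        X.to_numpy(), label=y, feature_names=list(matrix.values.columns)
    )
    booster = xgb.train(hp.to_xgb_params(), dtrain, num_boost_round=hp.n_rounds)
    return FoldModel(
        booster=booster,
        feature_names=list(matrix.values.columns),
        base_rate=float(y.mean()),
        fold=fold,
    )


def cross_validate(
    matrix: FeatureMatrix,
    labels: ResponseLabels,
    assignment: FoldAssignment,
    hyperparams: Hyperparams | None = None,
) -> tuple[pd.DataFrame, TrainedModelSet]:
    """Held-out predictions for every instance plus the per-fold models.

    Returns a DataFrame indexed like the feature matrix with columns
    ``prob`` (predicted response probability) and ``fold`` (provenance),
    and the TrainedModelSet. Every instance is predicted exactly once, by
    the fold that holds out its group.
    """
    groups = (
        matrix.tfs if assignment.by == "tf"
        else list(matrix.values.index.get_level_values("gene").unique())
    )
    missing = set(groups) - set(assignment.test_fold)
    if missing:
        raise ValueError(f"assignment does not cover groups: {sorted(missing)[:3]}")

    models: dict[int, FoldModel] = {}
    prob = pd.Series(np.nan, index=matrix.values.index, name="prob")
    fold_of = pd.Series(-1, index=matrix.values.index, name="fold")
    for fold in range(assignment.fold_count):
        try:
            model = train_fold(matrix, labels, fold, assignment, hyperparams)
        except ValueError as exc:
            raise ValueError(f"fold {fold}: {exc}") from exc
        models[fold] = model
        _, test_mask = _split_masks(matrix, assignment, fold)
        if not test_mask.any():
            continue
        X_test = matrix.values.loc[test_mask]
        dtest = xgb.DMatrix(
            X_test.to_numpy(), feature_names=list(matrix.values.columns)
        )
        prob.loc[test_mask] = model.booster.predict(dtest)
        fold_of.loc[test_mask] = fold

    predictions = pd.concat([prob, fold_of], axis=1)
    if predictions["prob"].isna().any():
        raise RuntimeError("some instances were never predicted")
    return predictions, TrainedModelSet(
        models=models,
        assignment=assignment,
        hyperparams=hyperparams or Hyperparams(),
    )
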