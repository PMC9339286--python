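"""Model/Results interface over the cross-validation and explanation machinery.

    >>> model = TFResponseModel(matrix, labels, config)
    >>> res = model.fit(seed=0)
    >>> res.pr.table  # per-TF AUPRC vs random expectation
    >>> sig = res.significance(n_perm=5, seed=1)
    >>> attr = res.explain()
    >>> print(res.summary())

``TFResponseModel`` holds the data (a FeatureMatrix of (TF, gene) instances
and their ResponseLabels); ``fit`` runs TF-grouped cross-validation with
gradient-boosted trees and returns a ``TFResponseResults`` carrying the
held-out predictions, per-TF precision-recall evaluation, and lazily
computed permutation-null significance and SHAP attributions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .build import Dataset, build_feature_matrix, build_labels, load_dataset
from .evaluation_null import (
    LsdFit,
    NullModel,
    PRResult,
    efficacy_report,
    fit_lsd,
    permutation_null,
    pr_by_tf,
    significance_table,
)
from .features import FeatureMatrix, select_feature_subset
from .io_formats import RunConfig
from .labels import BoundSet, ResponseLabels
from .model_cv import (
    FoldAssignment,
    Hyperparams,
    TrainedModelSet,
    cross_validate,
    make_gene_folds,
    make_tf_folds,
)
from .shap_explain import (
    AttributionMatrix,
    compute_attributions,
    net_influence_by_class,
)

__all__ = ["TFResponseModel", "TFResponseResults"]


class TFResponseModel:
    """Predicts which genes respond to perturbation of a TF.

    Parameters
    ----------
    matrix : FeatureMatrix
        (TF, gene) instances x features from unperturbed cells.
    labels : ResponseLabels
        Binary responsiveness per instance.
    config : RunConfig, optional
        Thresholds and fold/permutation counts; defaults are the published
        settings.
    """

    def __init__(
        self,
        matrix: FeatureMatrix,
        labels: ResponseLabels,
        config: RunConfig | None = None,
    ):
        self.config = config or RunConfig()
        missing = set(matrix.values.index) - set(labels.responsive.index)
        if missing:
            raise ValueError(f"labels missing for {len(missing)} instances")
        if self.config.feature_subset != "full":
            matrix = select_feature_subset(matrix, self.config.feature_subset)
        self.matrix = matrix
        self.labels = labels

    @classmethod
    def from_dataset(
        cls,
        data: Dataset,
        config: RunConfig | None = None,
        label_rule: str = "de",
    ) -> "TFResponseModel":
        config = config or RunConfig()
        matrix = build_feature_matrix(data, config)
        labels = build_labels(data, config, rule=label_rule)
        return cls(matrix, labels, config)

    @classmethod
    def from_directory(
        cls,
        root: str | Path,
        config: RunConfig | None = None,
        label_rule: str = "de",
        chrom_length: int | None = None,
    ) -> "TFResponseModel":
        return cls.from_dataset(load_dataset(root, chrom_length), config, label_rule)

    def fit(
        self,
        fold_count: int | None = None,
        seed: int | None = None,
        hyperparams: Hyperparams | None = None,
        cv_by: str = "tf",
    ) -> "TFResponseResults":
        """Run grouped cross-validation and evaluate held-out predictions."""
        cfg = self.config
        fold_count = fold_count or cfg.fold_count
        seed = cfg.seed if seed is None else seed
        hp = hyperparams or Hyperparams(
            n_rounds=cfg.n_boost_rounds, max_depth=cfg.max_depth, seed=seed
        )
        if cv_by == "tf":
            assignment = make_tf_folds(self.matrix.tfs, fold_count, seed)
        elif cv_by == "gene":
            assignment = make_gene_folds(self.matrix.genes, fold_count, seed)
        else:
            raise ValueError(f"unknown cv grouping {cv_by!r}")
        predictions, models = cross_validate(self.matrix, self.labels, assignment, hp)
        return TFResponseResults(model=self, predictions=predictions,
                                 models=models, hyperparams=hp)


@dataclass
class TFResponseResults:
    """Held-out predictions plus evaluation, significance, and explanation."""

    model: TFResponseModel
    predictions: pd.DataFrame  # columns prob, fold
    models: TrainedModelSet
    hyperparams: Hyperparams
    _pr: PRResult | None = field(default=None, repr=False)
    _null: NullModel | None = field(default=None, repr=False)
    _attr: dict[str, AttributionMatrix] = field(default_factory=dict, repr=False)

    @property
    def labels(self) -> ResponseLabels:
        return self.model.labels

    @property
    def pr(self) -> PRResult:
        """Per-TF AUPRC, its random expectation, and their ratio."""
        if self._pr is None:
            self._pr = pr_by_tf(self.predictions, self.labels)
        return self._pr

    def permutation_null(self, n_perm: int | None = None, seed: int = 0) -> NullModel:
        """Per-TF mean/SD of AUPRC over label-permuted refits (cached)."""
        n_perm = n_perm or self.model.config.permutation_count
        if self._null is None or self._null.permutation_count != n_perm:
            self._null = permutation_null(
                self.model.matrix, self.labels, self.models.assignment,
                n_perm=n_perm, seed=seed, hyperparams=self.hyperparams,
            )
        return self._null

    def lsd_fit(self, n_perm: int | None = None, seed: int = 0,
                variant: str = "ordinary") -> LsdFit:
        null = self.permutation_null(n_perm, seed)
        return fit_lsd(
            null, self.pr.table["random_expectation"], variant=variant,
            responder_floor=self.model.config.responder_floor,
        )

    def significance(
        self, n_perm: int | None = None, seed: int = 0, variant: str = "ordinary"
    ) -> pd.DataFrame:
        """Per-TF z, p, and significance flag against the permutation null."""
        null = self.permutation_null(n_perm, seed)
        lsd = self.lsd_fit(n_perm, seed, variant)
        return significance_table(
            self.pr, null, lsd,
            responder_floor=self.model.config.responder_floor,
            significance_p=self.model.config.significance_p,
        )

    def explain(self, output_space: str = "margin") -> AttributionMatrix:
        """SHAP attributions for every held-out instance (cached per space)."""
        if output_space not in self._attr:
            self._attr[output_space] = compute_attributions(
                self.models, self.model.matrix, output_space=output_space
            )
        return self._attr[output_space]

    def net_influence(self, group: str = "responsive",
                      bound: BoundSet | None = None) -> pd.DataFrame:
        """Net SHAP influence per (TF, feature class) for a gene group."""
        return net_influence_by_class(self.explain(), self.labels, group, bound)

    def efficacy(self) -> pd.DataFrame:
        return efficacy_report(self.pr, self.labels)

    def summary(self) -> str:
        """Human-readable per-TF evaluation table."""
        cfg = self.model.config
        pr = self.pr.table
        lines = [
            "TF perturbation response prediction",
            "=" * 65,
            f"mode: {cfg.mode}   instances: {len(self.predictions)}   "
            f"features: {self.model.matrix.values.shape[1]}",
            f"TFs: {len(pr)}   folds: {self.models.assignment.fold_count}   "
            f"boosting rounds: {self.hyperparams.n_rounds}",
            "-" * 65,
            f"{'TF':<12}{'AUPRC':>10}{'random':>10}{'ratio':>10}",
        ]
        for tf, row in pr.iterrows():
            lines.append(
                f"{tf:<12}{row['auprc']:>10.4f}"
                f"{row['random_expectation']:>10.4f}{row['ratio']:>10.2f}"
            )
        lines.append("-" * 65)
        lines.append(
            f"median AUPRC {pr['auprc'].median():.4f}   "
            f"median ratio to random {pr['ratio'].median():.2f}"
        )
        return "\n".join(lines)
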