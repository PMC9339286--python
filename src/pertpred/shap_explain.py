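"""SHAP attributions for the fold models and their published aggregations.

Attributions are computed with the TreeSHAP algorithm built into XGBoost
(``Booster.predict(pred_contribs=True)``), which is exact for tree
ensembles and satisfies local accuracy: for every instance, the base value
(expected model output over the training data) plus the per-feature
attributions equals the model's output. The default output space is the
margin (log-odds), where tree-path attribution is exact; a probability-space
view rescales each instance's attributions so they sum to the probability
deviation instead.

Every instance is explained by the fold model that held out its TF, so all
attributions are on genuinely unseen (TF, gene) pairs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import xgboost as xgb
from scipy import stats

from .features import FeatureMatrix, feature_class_of
from .labels import BoundSet, ResponseLabels
from .model_cv import FoldAssignment, TrainedModelSet
from .regions import GeneRegions

__all__ = [
    "AttributionMatrix",
    "InfluenceSummary",
    "compute_attributions",
    "signed_sums",
    "net_influence_by_class",
    "positional_profile",
    "bin_group_test",
    "updown_importance",
    "input_attribution_correlation",
]

GENE_GROUPS = (
    "responsive",
    "nonresponsive",
    "bound",
    "bound_responsive",
    "bound_nonresponsive",
    "all",
)


@dataclass
class AttributionMatrix:
    """Per-instance per-feature SHAP values, same shape as the feature matrix."""

    values: pd.DataFrame  # MultiIndex (tf, gene) rows, feature columns
    base_values: pd.Series  # per instance: expected model output
    output_space: str = "margin"  # {"margin", "probability"}

    def for_tf(self, tf: str) -> pd.DataFrame:
        return self.values.xs(tf, level="tf")

    def model_output(self) -> pd.Series:
        """base + sum of attributions, i.e. the explained model output."""
        return self.base_values + self.values.sum(axis=1)


@dataclass
class InfluenceSummary:
    """Signed SHAP sums per (tf, feature class, gene group).

    ``positive_sum``/``negative_sum``: mean over the group's genes of the sum
    of positive / negative per-bin SHAPs of the class. ``net_influence`` is
    their total (the sum of all SHAPs regardless of sign or position).
    ``global_importance`` is the mean |SHAP| over the class's columns.
    """

    table: pd.DataFrame  # MultiIndex (tf, feature_class, gene_group)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def compute_attributions(
    models: TrainedModelSet,
    matrix: FeatureMatrix,
    assignment: FoldAssignment | None = None,
    output_space: str = "margin",
) -> AttributionMatrix:
    """TreeSHAP attributions for every instance, by its held-out fold model.

    In probability space the margin attributions of each instance are
    rescaled by (sigmoid(margin) - sigmoid(base)) / (margin - base) and the
    base value is mapped through the logistic, preserving local accuracy.
    """
    if output_space not in {"margin", "probability"}:
        raise ValueError(f"unknown output space {output_space!r}")
    assignment = assignment or models.assignment
    columns = list(matrix.values.columns)
    values = pd.DataFrame(
        np.nan, index=matrix.values.index, columns=columns, dtype=float
    )
    base = pd.Series(np.nan, index=matrix.values.index, dtype=float)
    level = assignment.by
    groups = matrix.values.index.get_level_values(level)
    for fold in range(assignment.fold_count):
        test_set = set(assignment.test_groups(fold))
        mask = np.asarray(groups.isin(test_set))
        if not mask.any():
            continue
        model = models.models[fold]
        if model.feature_names != columns:
            raise ValueError(
                f"fold {fold}: model feature order does not match the matrix"
            )
        X = matrix.values.loc[mask]
        dm = xgb.DMatrix(X.to_numpy(), feature_names=columns)
        contribs = model.booster.predict(dm, pred_contribs=True)
        values.loc[mask, :] = contribs[:, :-1]
        base.loc[mask] = contribs[:, -1]
    if values.isna().any().any():
        raise RuntimeError("some instances were never explained")

    if output_space == "probability":
        margin_out = base.to_numpy() + values.to_numpy().sum(axis=1)
        b = base.to_numpy()
        delta = margin_out - b
        prob_delta = _sigmoid(margin_out) - _sigmoid(b)
        # derivative limit where the margin equals the base
        scale = np.where(
            np.abs(delta) > 1e-12,
            prob_delta / np.where(np.abs(delta) > 1e-12, delta, 1.0),
            _sigmoid(b) * (1.0 - _sigmoid(b)),
        )
        values = values.mul(pd.Series(scale, index=values.index), axis=0)
        base = pd.Series(_sigmoid(b), index=base.index)
    return AttributionMatrix(values=values, base_values=base, output_space=output_space)


def _gene_group_members(
    tf: str,
    genes: pd.Index,
    labels: ResponseLabels | None,
    bound: BoundSet | None,
    group: str,
) -> pd.Index:
    if group == "all":
        return genes
    resp = labels.for_tf(tf) if labels is not None else None
    bset = bound[tf] if bound is not None else None
    if group == "responsive":
        return genes[resp.loc[genes] == 1]
    if group == "nonresponsive":
        return genes[resp.loc[genes] == 0]
    if group == "bound":
        return genes[genes.isin(bset)]
    if group == "bound_responsive":
        return genes[genes.isin(bset) & (resp.loc[genes] == 1)]
    if group == "bound_nonresponsive":
        return genes[genes.isin(bset) & (resp.loc[genes] == 0)]
    raise ValueError(f"unknown gene group {group!r}")


def signed_sums(
    attr: AttributionMatrix,
    labels: ResponseLabels | None = None,
    bound: BoundSet | None = None,
    groups: tuple[str, ...] = ("responsive", "nonresponsive"),
    pool_dinuc: bool = True,
) -> InfluenceSummary:
    """Positive/negative SHAP sums per feature class, averaged over gene groups.

    For each gene, the positive SHAP values of a class are summed over all
    its positions (bins), and likewise the negatives; the summary reports
    the group means of those sums. Empty groups yield NaN with a warning.
    """
    classes = pd.Index(
        [feature_class_of(c, pool_dinuc) for c in attr.values.columns]
    )
    rows = {}
    for tf in attr.values.index.get_level_values("tf").unique():
        block = attr.for_tf(tf)
        genes = block.index
        for group in groups:
            members = _gene_group_members(tf, genes, labels, bound, group)
            if len(members) == 0:
                warnings.warn(f"empty gene group {group!r} for TF {tf!r}", stacklevel=2)
            sub = block.loc[members]
            for cls in classes.unique():
                cols = attr.values.columns[classes == cls]
                vals = sub[cols].to_numpy()
                if vals.size == 0 or len(members) == 0:
                    pos = neg = net = imp = np.nan
                else:
                    pos = float(np.clip(vals, 0, None).sum(axis=1).mean())
                    neg = float(np.clip(vals, None, 0).sum(axis=1).mean())
                    net = pos + neg
                    imp = float(np.abs(vals).mean())
                rows[(tf, cls, group)] = {
                    "positive_sum": pos,
                    "negative_sum": neg,
                    "net_influence": net,
                    "global_importance": imp,
                }
    table = pd.DataFrame(rows).T
    table.index.names = ["tf", "feature_class", "gene_group"]
    return InfluenceSummary(table=table)


def net_influence_by_class(
    attr: AttributionMatrix,
    labels: ResponseLabels,
    group: str = "responsive",
    bound: BoundSet | None = None,
    pool_dinuc: bool = True,
) -> pd.DataFrame:
    """Net influence per (tf, feature class) for one gene group (tf x class)."""
    summary = signed_sums(attr, labels, bound, groups=(group,), pool_dinuc=pool_dinuc)
    return (
        summary.table["net_influence"]
        .droplevel("gene_group")
        .unstack("feature_class")
    )


def _promoter_bin_columns(
    attr: AttributionMatrix, regions: GeneRegions, track: str
) -> list[tuple[tuple[int, int], str]]:
    out = []
    for (a, b), _ in regions.promoter_bins:
        col = f"{track}:prom_{a}:{b}"
        if col in attr.values.columns:
            out.append(((a, b), col))
    return out


def positional_profile(
    attr: AttributionMatrix,
    regions: GeneRegions,
    tf: str,
    gene_group: pd.Index | set,
    track: str = "tf_binding",
) -> pd.Series:
    """Mean signed SHAP per promoter bin of ``track`` over a gene group.

    Bins are ordered 5'->3'. An empty group returns an all-NaN profile.
    """
    cols = _promoter_bin_columns(attr, regions, track)
    block = attr.for_tf(tf)
    members = block.index[block.index.isin(set(gene_group))]
    index = [f"{a}:{b}" for (a, b), _ in cols]
    if len(members) == 0:
        return pd.Series(np.nan, index=index, name=tf)
    means = [float(block.loc[members, col].mean()) for _, col in cols]
    return pd.Series(means, index=index, name=tf)


def _rank_sum_greater(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """One-sided Wilcoxon rank-sum (x > y); exact when both n <= 10."""
    method = "exact" if (len(x) <= 10 and len(y) <= 10) else "asymptotic"
    try:
        res = stats.mannwhitneyu(x, y, alternative="greater", method=method)
    except ValueError:
        # exact method refuses ties; fall back to the tie-corrected normal
        res = stats.mannwhitneyu(x, y, alternative="greater", method="asymptotic")
    return float(res.statistic), float(res.pvalue)


def bin_group_test(
    attr: AttributionMatrix,
    tf: str,
    bound_responsive: set,
    bound_nonresponsive: set,
    track: str = "tf_binding",
    regions: GeneRegions | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per promoter bin: are SHAPs higher for bound-responsive genes?

    One-sided Wilcoxon rank-sum (responsive > nonresponsive) per bin; the
    attribute ``n_significant`` on the returned frame counts bins with
    p < alpha. Either group empty -> all-NaN result.
    """
    block = attr.for_tf(tf)
    if regions is not None:
        cols = [c for _, c in _promoter_bin_columns(attr, regions, track)]
    else:
        cols = [c for c in block.columns
                if c.startswith(f"{track}:prom_")]
    resp = block.index[block.index.isin(bound_responsive)]
    nonresp = block.index[block.index.isin(bound_nonresponsive)]
    rows = {}
    for col in cols:
        if len(resp) == 0 or len(nonresp) == 0:
            rows[col] = {"statistic": np.nan, "p": np.nan}
            continue
        u, p = _rank_sum_greater(
            block.loc[resp, col].to_numpy(), block.loc[nonresp, col].to_numpy()
        )
        rows[col] = {"statistic": u, "p": p}
    out = pd.DataFrame(rows).T
    out.attrs["n_significant"] = int((out["p"] < alpha).sum())
    return out


def updown_importance(
    attr: AttributionMatrix,
    regions: GeneRegions,
    feature_class: str,
) -> tuple[pd.DataFrame, float]:
    """Global importance of a class upstream vs downstream of the TSS.

    Per TF, the mean |SHAP| over all genes and all promoter bins on each
    side of the TSS (upstream: bins ending at or before the TSS; downstream:
    bins starting at or after it). Returns the per-TF table and the
    across-TF one-sided Wilcoxon rank-sum p-value for downstream > upstream.
    """
    up_cols, dn_cols = [], []
    for (a, b), col in _promoter_bin_columns(attr, regions, feature_class):
        if b <= 0:
            up_cols.append(col)
        elif a >= 0:
            dn_cols.append(col)
    if not up_cols and not dn_cols:
        raise ValueError(f"no promoter-bin columns for class {feature_class!r}")
    rows = {}
    for tf in attr.values.index.get_level_values("tf").unique():
        block = attr.for_tf(tf)
        rows[tf] = {
            "upstream": float(np.abs(block[up_cols].to_numpy()).mean()) if up_cols else 0.0,
            "downstream": float(np.abs(block[dn_cols].to_numpy()).mean()) if dn_cols else 0.0,
        }
    table = pd.DataFrame(rows).T
    _, p = _rank_sum_greater(
        table["downstream"].to_numpy(), table["upstream"].to_numpy()
    )
    return table, p


def input_attribution_correlation(
    attr: AttributionMatrix,
    matrix: FeatureMatrix,
    feature: str,
) -> pd.Series:
    """Spearman correlation between a feature's values and its SHAPs, per TF.

    NaN for TFs whose instances have zero variance in the feature.
    """
    if feature not in matrix.values.columns:
        raise KeyError(f"unknown feature {feature!r}")
    out = {}
    for tf in attr.values.index.get_level_values("tf").unique():
        x = matrix.values.xs(tf, level="tf")[feature]
        s = attr.for_tf(tf)[feature].loc[x.index]
        if x.nunique() <= 1 or s.nunique() <= 1:
            out[tf] = np.nan
            continue
        rho, _ = stats.spearmanr(x.to_numpy(), s.to_numpy())
        out[tf] = float(rho)
    return pd.Series(out, name=feature)
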