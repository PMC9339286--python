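"""Per-TF precision-recall evaluation and permutation-based significance.

The accuracy summary is the area under the precision-recall curve (AUPRC),
estimated by average precision (step-wise sum of precision at each positive,
ties grouped; no trapezoidal interpolation). Its random expectation for a TF
is that TF's response fraction. Significance is assessed against a
permutation null: responsive labels are shuffled within each TF (preserving
the number of responders), the full cross-validation is rerun, and the
standard deviation of the permuted AUPRCs is modelled as a linear function
of log response fraction (the "LSD" fit). The per-TF p-value is the upper
tail of a normal centred at the analytic expectation (the response
fraction) with the model-predicted SD — or the TF's own empirical permuted
SD when fewer than the responder floor (1%) of genes respond.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import average_precision_score

from .features import FeatureMatrix
from .labels import ResponseLabels
from .model_cv import FoldAssignment, Hyperparams, cross_validate

__all__ = [
    "PRResult",
    "NullModel",
    "LsdFit",
    "TfSignificance",
    "auprc",
    "pr_by_tf",
    "permute_labels",
    "permutation_null",
    "fit_lsd",
    "tf_pvalue",
    "significance_table",
    "efficacy_report",
]


@dataclass
class PRResult:
    """Per-TF AUPRC with its random expectation (the response fraction)."""

    table: pd.DataFrame  # index tf; columns auprc, random_expectation, ratio


@dataclass
class NullModel:
    """Permuted-label AUPRC mean/SD per TF."""

    stats: pd.DataFrame  # index tf; columns mean, sd
    permutation_count: int
    seed: int


@dataclass
class LsdFit:
    """Linear model log(SD) = intercept + slope * log(response fraction)."""

    slope: float
    intercept: float
    variant: str = "ordinary"  # {"ordinary", "conservative_quintile_max"}

    def predict_sd(self, fraction: float) -> float:
        return float(np.exp(self.intercept + self.slope * np.log(fraction)))


@dataclass
class TfSignificance:
    z: float
    p: float
    significant: bool
    sd_source: str  # {"model", "empirical"}


def auprc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Average-precision AUPRC; requires at least one positive and negative.

    All-equal scores give exactly the prevalence (a single threshold with
    precision = prevalence at recall 1), which anchors the permutation null.
    """
    labels = np.asarray(labels)
    scores = np.asarray(scores)
    if labels.sum() == 0:
        raise ValueError("AUPRC undefined with zero positive labels")
    if labels.sum() == len(labels):
        raise ValueError("AUPRC undefined with zero negative labels")
    return float(average_precision_score(labels, scores))


def pr_by_tf(predictions: pd.DataFrame, labels: ResponseLabels) -> PRResult:
    """AUPRC, random expectation, and their ratio for every TF."""
    rows = {}
    for tf in labels.tfs:
        y = labels.for_tf(tf)
        s = predictions["prob"].xs(tf, level="tf").loc[y.index]
        frac = float(y.mean())
        a = auprc(s.to_numpy(), y.to_numpy())
        rows[tf] = {"auprc": a, "random_expectation": frac,
                    "ratio": a / frac if frac > 0 else np.nan}
    return PRResult(table=pd.DataFrame(rows).T.sort_index())


def permute_labels(labels: ResponseLabels, seed: int) -> ResponseLabels:
    """Shuffle responsive flags within each TF, preserving responder counts."""
    rng = np.random.default_rng(seed)
    pieces = {}
    for tf in labels.tfs:
        y = labels.for_tf(tf)
        pieces[tf] = pd.Series(rng.permutation(y.to_numpy()), index=y.index)
    permuted = pd.concat(pieces, names=["tf", "gene"])
    return ResponseLabels(
        responsive=permuted, perturbation_efficacy=dict(labels.perturbation_efficacy)
    )


def permutation_null(
    matrix: FeatureMatrix,
    labels: ResponseLabels,
    assignment: FoldAssignment,
    n_perm: int,
    seed: int,
    hyperparams: Hyperparams | None = None,
) -> NullModel:
    """Rerun the full cross-validation on label-permuted data ``n_perm`` times.

    Features and fold assignment stay fixed; only the labels move. Returns
    the per-TF mean and SD of the permuted AUPRCs.
    """
    if n_perm < 2:
        raise ValueError("need at least 2 permutations for a standard deviation")
    rng = np.random.default_rng(seed)
    per_tf: dict[str, list[float]] = {tf: [] for tf in labels.tfs}
    for _ in range(n_perm):
        perm = permute_labels(labels, seed=int(rng.integers(2**31 - 1)))
        preds, _ = cross_validate(matrix, perm, assignment, hyperparams)
        pr = pr_by_tf(preds, perm)
        for tf in labels.tfs:
            per_tf[tf].append(pr.table.loc[tf, "auprc"])
    table = pd.DataFrame(
        {
            tf: {"mean": float(np.mean(v)), "sd": float(np.std(v, ddof=1))}
            for tf, v in per_tf.items()
        }
    ).T.sort_index()
    return NullModel(stats=table, permutation_count=n_perm, seed=seed)


def _quintile_maxima(log_f: np.ndarray, log_sd: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-quintile maximum log SD, quintiles on response fraction with
    right-closed breaks at the 20/40/60/80th percentiles."""
    breaks = np.percentile(log_f, [20, 40, 60, 80])
    edges = np.concatenate([[-np.inf], breaks, [np.inf]])
    xs, ys = [], []
    for lo, hi in zip(edges[:-1], edges[1:]):
        in_q = (log_f > lo) & (log_f <= hi)
        if not in_q.any():
            continue
        i = np.argmax(log_sd[in_q])
        xs.append(log_f[in_q][i])
        ys.append(log_sd[in_q][i])
    return np.asarray(xs), np.asarray(ys)


def fit_lsd(
    null: NullModel,
    fractions: pd.Series,
    variant: str = "ordinary",
    responder_floor: float = 0.01,
) -> LsdFit:
    """Fit log SD of the permuted AUPRC as a linear function of log fraction.

    Only TFs at or above the responder floor enter the fit (below it the SDs
    no longer follow the trend and their empirical SD is used directly).
    ``conservative_quintile_max`` fits through only the highest-SD TF in
    each quintile of response fraction.
    """
    keep = fractions[fractions >= responder_floor]
    keep = keep[null.stats.loc[keep.index, "sd"] > 0]
    if len(keep) < 2:
        raise ValueError("need >= 2 TFs at/above the responder floor for the LSD fit")
    log_f = np.log(keep.to_numpy(dtype=float))
    log_sd = np.log(null.stats.loc[keep.index, "sd"].to_numpy(dtype=float))
    if variant == "conservative_quintile_max":
        log_f, log_sd = _quintile_maxima(log_f, log_sd)
        if len(log_f) < 2:
            raise ValueError("need >= 2 populated quintiles for the conservative fit")
    elif variant != "ordinary":
        raise ValueError(f"unknown LSD variant {variant!r}")
    slope, intercept = np.polyfit(log_f, log_sd, deg=1)
    return LsdFit(slope=float(slope), intercept=float(intercept), variant=variant)


def tf_pvalue(
    real_auprc: float,
    fraction: float,
    null_sd_empirical: float,
    lsd: LsdFit,
    responder_floor: float = 0.01,
    significance_p: float = 1e-3,
) -> TfSignificance:
    """One-sided upper-tail normal p-value for one TF's real AUPRC.

    Null mean is the analytic expectation (the response fraction); the SD
    comes from the LSD model, except for TFs under the responder floor,
    which use their own empirical permuted SD.
    """
    if fraction >= responder_floor:
        sd = lsd.predict_sd(fraction)
        sd_source = "model"
    else:
        sd = null_sd_empirical
        sd_source = "empirical"
    if sd <= 0 or not np.isfinite(sd):
        raise ValueError(f"null SD must be positive, got {sd}")
    z = (real_auprc - fraction) / sd
    p = float(np.clip(stats.norm.sf(z), np.nextafter(0, 1), 1.0))
    return TfSignificance(
        z=float(z), p=p, significant=p < significance_p, sd_source=sd_source
    )


def significance_table(
    pr: PRResult,
    null: NullModel,
    lsd: LsdFit,
    responder_floor: float = 0.01,
    significance_p: float = 1e-3,
) -> pd.DataFrame:
    """Per-TF significance (z, p, flag, SD source) as one DataFrame."""
    rows = {}
    for tf, row in pr.table.iterrows():
        sig = tf_pvalue(
            real_auprc=row["auprc"],
            fraction=row["random_expectation"],
            null_sd_empirical=float(null.stats.loc[tf, "sd"]),
            lsd=lsd,
            responder_floor=responder_floor,
            significance_p=significance_p,
        )
        rows[tf] = {
            "z": sig.z, "p": sig.p, "significant": sig.significant,
            "sd_source": sig.sd_source,
        }
    return pd.DataFrame(rows).T.sort_index()


def efficacy_report(pr: PRResult, labels: ResponseLabels) -> pd.DataFrame:
    """One row per TF: AUPRC, ratio to random, and perturbation efficacy.

    Efficacy is the |log2FC| of the perturbed TF's own gene (NaN when that
    gene is absent from the DE table).
    """
    table = pr.table.copy()
    table["efficacy"] = [
        labels.perturbation_efficacy.get(tf, np.nan) for tf in table.index
    ]
    return table.sort_index()
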