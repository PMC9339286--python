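"""End-to-end benchmark runs on the synthetic presets.

These drivers reproduce the package's headline checks from scratch at
desk scale: structural properties of the region schemes and the
cross-validation design, planted-signal recovery on the binding-dominant
(yeastlike) and expression-dominant (humanlike) presets, permutation-null
calibration, and significance-machinery diagnostics. Both the acceptance
script and the acceptance test suite run through these functions.

Problem sizes here are the generator defaults (1,000 genes x 10 TFs
yeastlike; 800 x 8 humanlike; 2,000 x 4 for null calibration) with a
reduced boosting profile (150 rounds, depth 4; 60 x depth 3 for the
permuted-label refits, whose calibration does not depend on model
capacity). The library's default hyperparameters are larger; see
docs/methods.md.
"""

from __future__ import annotations

import dataclasses
import tempfile
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .build import build_gene_regions, build_labels, build_feature_matrix, load_dataset
from .evaluation_null import LsdFit, NullModel, auprc, fit_lsd, tf_pvalue
from .io_formats import RunConfig, TssRecord
from .labels import bound_gene_set
from .model import TFResponseModel
from .model_cv import Hyperparams, make_tf_folds
from .regions import (
    HUMAN_AGGREGATED_SCHEME,
    HUMAN_BINNED_SCHEME,
    YEAST_SCHEME,
    build_regions,
    count_features,
)
from .shap_explain import input_attribution_correlation
from .synthetic_data import HUMANLIKE, YEASTLIKE, simulate_dataset

ACCEPT_HP = Hyperparams(n_rounds=150, max_depth=4)
NULL_HP = Hyperparams(n_rounds=60, max_depth=3)


def structural_report() -> dict[str, float]:
    """Region-scheme and CV-design counts, computed from the schemes."""
    tss = TssRecord("g", "chr", 600_000, "+")
    yeast = build_regions(tss, [], YEAST_SCHEME, 2_000_000)
    agg = build_regions(tss, [], HUMAN_AGGREGATED_SCHEME, 2_000_000)
    binned = build_regions(tss, [], HUMAN_BINNED_SCHEME, 2_000_000)
    prom = agg.promoter_interval
    edges = HUMAN_BINNED_SCHEME.enhancer_bin_edges()
    widths = np.diff(edges)
    folds = make_tf_folds([f"T{k}" for k in range(20)], fold_count=10, seed=0)
    train_share = np.mean(
        [len(folds.train_groups(f)) / 20 for f in range(10)]
    )
    return {
        "yeast_promoter_bins_per_track": float(len(yeast.promoter_bins)),
        "human_promoter_window_bp": float(prom.end - prom.start),
        "human_promoter_bins": float(len(agg.promoter_bins)),
        "enhancer_bins_per_side": float(HUMAN_BINNED_SCHEME.enhancer_bin_count),
        "enhancer_first_bin_width_kb": float(widths[0] / 1000),
        "enhancer_bin_width_increment_kb": float((widths[1] - widths[0]) / 1000),
        "aggregated_enhancer_features": float(
            count_features(agg, HUMAN_AGGREGATED_SCHEME) - len(agg.promoter_bins)
        ),
        "human_binned_features_per_track": float(
            count_features(binned, HUMAN_BINNED_SCHEME)
        ),
        "cv_train_tf_percent": float(100 * train_share),
    }


def _fit_preset(preset, config: RunConfig, seed: int, workdir: Path,
                subset: str = "full"):
    cfg = dataclasses.replace(preset, seed=seed)
    sim = simulate_dataset(cfg, workdir / cfg.preset)
    data = load_dataset(sim.out_dir, chrom_length=sim.paths["chrom_length"])
    matrix = build_feature_matrix(data, config)
    labels = build_labels(data, config)
    run_cfg = dataclasses.replace(config, feature_subset=subset)
    model = TFResponseModel(matrix, labels, run_cfg)
    hp = dataclasses.replace(ACCEPT_HP, seed=seed)
    res = model.fit(seed=seed, hyperparams=hp)
    return sim, data, matrix, labels, res


def yeastlike_recovery(seed: int, workdir: Path) -> dict:
    """Binding-dominant preset: accuracy vs chance and SHAP dominance."""
    config = RunConfig(mode="yeast", fold_count=10, enhancer_scheme="none",
                       seed=seed)
    sim, data, matrix, labels, res = _fit_preset(YEASTLIKE, config, seed, workdir)
    pr = res.pr.table
    influence = res.net_influence("responsive").mean()
    attr = res.explain()
    rho_level = input_attribution_correlation(attr, matrix, "gex_level:gene")
    rho_var = input_attribution_correlation(attr, matrix, "gex_var:gene")
    # SHAP local accuracy across every explained instance
    local_err = _local_accuracy_error(res)
    regions = build_gene_regions(data, YEAST_SCHEME)
    bound = bound_gene_set(data.peaks, regions, min_signal=2.0)
    from .shap_explain import positional_profile

    any_regions = next(iter(regions.values()))
    peak_bins = []
    for tf in matrix.tfs:
        profile = positional_profile(attr, any_regions, tf, bound[tf])
        if profile.notna().any():
            peak_bins.append(profile.idxmax())
    return {
        "pr": pr,
        "influence": influence,
        "frac_tfs_auprc_gt_2x": float((pr["ratio"] > 2).mean()),
        "median_ratio": float(pr["ratio"].median()),
        "median_response_fraction": float(pr["random_expectation"].median()),
        "binding_influence_rank": int(
            (influence.sort_values(ascending=False).index == "tf_binding").argmax()
        ),
        "rho_gex_level": rho_level,
        "rho_gex_var": rho_var,
        "local_accuracy_max_abs_err": local_err,
        "binding_profile_peak_bins": peak_bins,
    }


def humanlike_recovery(seed: int, workdir: Path) -> dict:
    """Expression-dominant preset: ablation contrast and SHAP dominance."""
    config = RunConfig(mode="human", fold_count=8, enhancer_scheme="aggregated",
                       seed=seed)
    sim, data, matrix, labels, res_full = _fit_preset(
        HUMANLIKE, config, seed, workdir
    )
    hp = dataclasses.replace(ACCEPT_HP, seed=seed)
    out = {"full": res_full}
    for subset in ("gex_only", "binding_only"):
        cfg = dataclasses.replace(config, feature_subset=subset)
        out[subset] = TFResponseModel(matrix, labels, cfg).fit(
            seed=seed, hyperparams=hp
        )
    full = res_full.pr.table
    gex = out["gex_only"].pr.table
    bind = out["binding_only"].pr.table
    influence = res_full.net_influence("responsive").mean()
    attr = res_full.explain()
    return {
        "results": out,
        "influence": influence,
        "gex_over_full_median": float((gex["auprc"] / full["auprc"]).median()),
        "frac_tfs_gex_ge_090_full": float(
            (gex["auprc"] >= 0.9 * full["auprc"]).mean()
        ),
        "frac_tfs_binding_lt_15x": float((bind["ratio"] < 1.5).mean()),
        "median_response_fraction": float(full["random_expectation"].median()),
        "top_influence_classes": list(
            influence.sort_values(ascending=False).index[:2]
        ),
        "rho_gex_level": input_attribution_correlation(attr, matrix, "gex_level:gene"),
        "rho_gex_var": input_attribution_correlation(attr, matrix, "gex_var:gene"),
    }


def _local_accuracy_error(res) -> float:
    import xgboost as xgb

    attr = res.explain()
    matrix = res.model.matrix
    errs = []
    for fold in range(res.models.assignment.fold_count):
        for tf in res.models.assignment.test_groups(fold):
            X = matrix.for_tf(tf)
            dm = xgb.DMatrix(X.to_numpy(), feature_names=list(X.columns))
            margin = res.models.models[fold].booster.predict(dm, output_margin=True)
            explained = attr.model_output().xs(tf, level="tf").to_numpy()
            errs.append(float(np.max(np.abs(explained - margin))))
    return float(max(errs))


def null_calibration(seed: int, workdir: Path, n_perm: int = 50) -> dict:
    """Permuted-label AUPRC calibration at 2,000 genes, 50 permutations."""
    cfg = dataclasses.replace(
        YEASTLIKE, n_genes=2000, n_tfs=4, seed=seed + 101
    )
    sim = simulate_dataset(cfg, workdir / "nullcal")
    data = load_dataset(sim.out_dir, chrom_length=sim.paths["chrom_length"])
    config = RunConfig(mode="yeast", fold_count=4, enhancer_scheme="none",
                       seed=seed)
    matrix = build_feature_matrix(data, config)
    labels = build_labels(data, config)
    model = TFResponseModel(matrix, labels, config)
    hp = dataclasses.replace(NULL_HP, seed=seed)
    res = model.fit(seed=seed, hyperparams=hp)
    null = res.permutation_null(n_perm=n_perm, seed=seed)
    fracs = res.pr.table["random_expectation"]
    diffs = (null.stats["mean"] - fracs).abs()
    return {
        "null": null,
        "fractions": fracs,
        "max_abs_mean_minus_fraction": float(diffs.max()),
    }


def pvalue_uniformity(seed: int, n_reps: int = 200) -> float:
    """KS p-value for the permutation->LSD->normal-tail chain on its null."""
    rng = np.random.default_rng(seed)
    slope, intercept = 0.8, -1.0
    pvals = []
    for _ in range(n_reps):
        fracs = pd.Series(
            rng.uniform(0.02, 0.2, 12), index=[f"T{i}" for i in range(12)]
        )
        sd_true = np.exp(intercept + slope * np.log(fracs.to_numpy()))
        perm = rng.normal(
            fracs.to_numpy()[:, None], sd_true[:, None], size=(12, 30)
        )
        table = pd.DataFrame(
            {"mean": perm.mean(axis=1), "sd": perm.std(axis=1, ddof=1)},
            index=fracs.index,
        )
        null = NullModel(stats=table, permutation_count=30, seed=0)
        lsd = fit_lsd(null, fracs)
        tf = fracs.index[0]
        real = float(rng.normal(fracs[tf], sd_true[0]))
        pvals.append(tf_pvalue(real, float(fracs[tf]), table.loc[tf, "sd"], lsd).p)
    return float(stats.kstest(pvals, "uniform").pvalue)


def lsd_recovery() -> dict[str, float]:
    """Exact recovery of a planted log-SD line (ordinary and conservative)."""
    fractions = pd.Series(
        np.linspace(0.02, 0.3, 15), index=[f"T{i}" for i in range(15)]
    )
    sd = np.exp(-1.0 + 0.8 * np.log(fractions.to_numpy()))
    table = pd.DataFrame({"mean": fractions, "sd": sd}, index=fractions.index)
    null = NullModel(stats=table, permutation_count=10, seed=0)
    fit = fit_lsd(null, fractions)
    fit_c = fit_lsd(null, fractions, variant="conservative_quintile_max")
    return {
        "slope_error": abs(fit.slope - 0.8),
        "intercept_error": abs(fit.intercept + 1.0),
        "conservative_slope_error": abs(fit_c.slope - 0.8),
        "conservative_intercept_error": abs(fit_c.intercept + 1.0),
    }
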