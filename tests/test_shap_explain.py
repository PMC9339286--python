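import itertools
import json
import math

import numpy as np
import pandas as pd
import pytest
import xgboost as xgb

from pertpred.features import FeatureMatrix
from pertpred.labels import BoundSet, ResponseLabels
from pertpred.model_cv import Hyperparams, cross_validate, make_tf_folds
from pertpred.regions import YEAST_SCHEME, build_regions
from pertpred.io_formats import TssRecord
from pertpred.shap_explain import (
    AttributionMatrix,
    bin_group_test,
    compute_attributions,
    input_attribution_correlation,
    positional_profile,
    signed_sums,
    updown_importance,
)

FAST = Hyperparams(n_rounds=40, max_depth=3, seed=0)


# ---------------------------------------------------------------------------
# Exhaustive-subset Shapley oracle (independent of pred_contribs)
# ---------------------------------------------------------------------------

def _tree_expectation(node, x, known: set[int]):
    """Cover-weighted conditional expectation of one tree given features in
    ``known`` fixed at x; unknown splits average children by training cover."""
    if "leaf" in node:
        return node["leaf"]
    feat = int(node["split"].lstrip("f"))
    kids = {k["nodeid"]: k for k in node["children"]}
    if feat in known:
        # xgboost routes after casting the feature value to float32
        goes_left = np.float32(x[feat]) < np.float32(node["split_condition"])
        nxt = node["yes"] if goes_left else node["no"]
        return _tree_expectation(kids[nxt], x, known)
    left, right = kids[node["yes"]], kids[node["no"]]
    total = left["cover"] + right["cover"]
    return (
        left["cover"] * _tree_expectation(left, x, known)
        + right["cover"] * _tree_expectation(right, x, known)
    ) / total


def brute_force_shapley(booster: xgb.Booster, x: np.ndarray) -> np.ndarray:
    """Shapley values by enumerating all feature subsets over all trees."""
    dumps = booster.get_dump(dump_format="json", with_stats=True)
    p = len(x)
    phi = np.zeros(p)
    for dump in dumps:
        tree = json.loads(dump)

        def v(subset: frozenset) -> float:
            return _tree_expectation(tree, x, set(subset))

        for i in range(p):
            others = [j for j in range(p) if j != i]
            for r in range(len(others) + 1):
                for S in itertools.combinations(others, r):
                    w = (
                        math.factorial(len(S))
                        * math.factorial(p - len(S) - 1)
                        / math.factorial(p)
                    )
                    phi[i] += w * (v(frozenset(S) | {i}) - v(frozenset(S)))
    return phi


def _fit_booster(X, y, rounds, depth, seed=0):
    dm = xgb.DMatrix(X, label=y)
    return xgb.train(
        {
            "objective": "binary:logistic",
            "max_depth": depth,
            "eta": 0.3,
            "seed": seed,
            "nthread": 1,
            "base_score": 0.5,
        },
        dm,
        num_boost_round=rounds,
    )


class TestStumpOracle:
    def test_depth1_tree_matches_exhaustive_shapley(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(200, 2))
        y = (X[:, 0] > 0).astype(int)
        booster = _fit_booster(X, y, rounds=1, depth=1)
        contribs = booster.predict(xgb.DMatrix(X[:5]), pred_contribs=True)
        for i in range(5):
            oracle = brute_force_shapley(booster, X[i])
            np.testing.assert_allclose(contribs[i, :-1], oracle, atol=1e-6)

    def test_depth2_ensemble_matches_exhaustive_shapley(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(300, 4))
        y = ((X[:, 0] + X[:, 1] * X[:, 2]) > 0).astype(int)
        booster = _fit_booster(X, y, rounds=3, depth=2)
        contribs = booster.predict(xgb.DMatrix(X[:8]), pred_contribs=True)
        for i in range(8):
            oracle = brute_force_shapley(booster, X[i])
            np.testing.assert_allclose(contribs[i, :-1], oracle, atol=1e-6)


# ---------------------------------------------------------------------------
# Attribution computation on the CV models
# ---------------------------------------------------------------------------

def _cv_problem(n_tfs=3, n_genes=150, seed=0):
    rng = np.random.default_rng(seed)
    tfs = [f"T{k}" for k in range(n_tfs)]
    genes = [f"G{i}" for i in range(n_genes)]
    index = pd.MultiIndex.from_product([tfs, genes], names=["tf", "gene"])
    cols = [
        "tf_binding:prom_-200:-100",
        "tf_binding:prom_-100:0",
        "H3K4me3:prom_0:100",
        "gex_level:gene",
        "gex_var:gene",
    ]
    X = pd.DataFrame(rng.normal(size=(len(index), len(cols))), index=index,
                     columns=cols)
    logit = 1.5 * X["tf_binding:prom_-100:0"] + 1.0 * X["gex_level:gene"] + 0.5 * X[
        "gex_var:gene"] - 1.5
    y = pd.Series(
        (rng.random(len(index)) < 1 / (1 + np.exp(-logit))).astype(int), index=index
    )
    matrix = FeatureMatrix(values=X)
    labels = ResponseLabels(responsive=y)
    assignment = make_tf_folds(tfs, n_tfs, seed=seed)
    preds, models = cross_validate(matrix, labels, assignment, FAST)
    return matrix, labels, models


@pytest.fixture(scope="module")
def cv_attr():
    matrix, labels, models = _cv_problem()
    attr = compute_attributions(models, matrix)
    return matrix, labels, models, attr


class TestComputeAttributions:
    def test_local_accuracy_in_margin_space(self, cv_attr):
        matrix, _, models, attr = cv_attr
        for fold in range(models.assignment.fold_count):
            test_tfs = models.assignment.test_groups(fold)
            for tf in test_tfs:
                X = matrix.for_tf(tf)
                dm = xgb.DMatrix(X.to_numpy(), feature_names=list(X.columns))
                margin = models.models[fold].booster.predict(dm, output_margin=True)
                explained = attr.model_output().xs(tf, level="tf").to_numpy()
                np.testing.assert_allclose(explained, margin, atol=1e-6)

    def test_probability_space_local_accuracy(self, cv_attr):
        matrix, _, models, _ = cv_attr
        attr = compute_attributions(models, matrix, output_space="probability")
        for fold in range(models.assignment.fold_count):
            for tf in models.assignment.test_groups(fold):
                X = matrix.for_tf(tf)
                dm = xgb.DMatrix(X.to_numpy(), feature_names=list(X.columns))
                prob = models.models[fold].booster.predict(dm)
                explained = attr.model_output().xs(tf, level="tf").to_numpy()
                np.testing.assert_allclose(explained, prob, atol=1e-6)

    def test_dimensions_match_feature_matrix(self, cv_attr):
        matrix, _, _, attr = cv_attr
        assert attr.values.shape == matrix.values.shape
        assert list(attr.values.columns) == list(matrix.values.columns)

    def test_zero_split_ensemble_all_zero(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(100, 3))
        y = rng.integers(0, 2, 100)
        booster = xgb.train(
            {"objective": "binary:logistic", "max_depth": 1, "eta": 0.1,
             "gamma": 1e9, "nthread": 1},  # huge gamma: no split is worth it
            xgb.DMatrix(X, label=y), num_boost_round=3,
        )
        contribs = booster.predict(xgb.DMatrix(X), pred_contribs=True)
        np.testing.assert_allclose(contribs[:, :-1], 0.0, atol=1e-9)
        assert np.ptp(contribs[:, -1]) == 0.0  # constant base value


class TestSignedSums:
    def test_arithmetic_on_known_attributions(self):
        index = pd.MultiIndex.from_tuples(
            [("T0", "G0"), ("T0", "G1")], names=["tf", "gene"]
        )
        values = pd.DataFrame(
            {
                "H3K4me3:prom_-100:0": [0.1, 0.15],
                "H3K4me3:prom_0:100": [0.2, 0.10],
                "H3K4me3:prom_100:200": [-0.05, 0.0],
            },
            index=index,
        )
        attr = AttributionMatrix(
            values=values, base_values=pd.Series(0.0, index=index)
        )
        labels = ResponseLabels(responsive=pd.Series([1, 1], index=index))
        summary = signed_sums(attr, labels, groups=("responsive",))
        row = summary.table.loc[("T0", "H3K4me3", "responsive")]
        assert row["positive_sum"] == pytest.approx((0.3 + 0.25) / 2)
        assert row["negative_sum"] == pytest.approx(-0.025)
        assert row["net_influence"] == pytest.approx(
            row["positive_sum"] + row["negative_sum"], abs=1e-10
        )

    def test_all_zero_attributions_give_zero_summaries(self):
        index = pd.MultiIndex.from_tuples([("T0", "G0")], names=["tf", "gene"])
        attr = AttributionMatrix(
            values=pd.DataFrame({"gex_level:gene": [0.0]}, index=index),
            base_values=pd.Series(0.0, index=index),
        )
        labels = ResponseLabels(responsive=pd.Series([1], index=index))
        summary = signed_sums(attr, labels, groups=("responsive",))
        assert (summary.table[["positive_sum", "negative_sum", "net_influence"]]
                .eq(0).all().all())

    def test_empty_group_warns_and_gives_nan(self):
        index = pd.MultiIndex.from_tuples([("T0", "G0")], names=["tf", "gene"])
        attr = AttributionMatrix(
            values=pd.DataFrame({"gex_level:gene": [0.5]}, index=index),
            base_values=pd.Series(0.0, index=index),
        )
        labels = ResponseLabels(responsive=pd.Series([1], index=index))
        with pytest.warns(UserWarning, match="empty gene group"):
            summary = signed_sums(attr, labels, groups=("nonresponsive",))
        assert summary.table["net_influence"].isna().all()

    def test_completeness_over_classes(self, cv_attr):
        """Sum of class net influences equals mean(model output - base)."""
        _, labels, _, attr = cv_attr
        summary = signed_sums(attr, labels, groups=("all",))
        for tf in labels.tfs:
            total = summary.table.xs((tf, "all"), level=("tf", "gene_group"))[
                "net_influence"
            ].sum()
            block = attr.for_tf(tf)
            expected = float(
                (attr.model_output().xs(tf, level="tf")
                 - attr.base_values.xs(tf, level="tf")).mean()
            )
            assert total == pytest.approx(expected, abs=1e-10)


class TestPositionalProfile:
    @pytest.fixture
    def regions(self):
        return build_regions(
            TssRecord("g", "chr1", 10_000, "+"), [], YEAST_SCHEME, 1_000_000
        )

    def _attr(self, values, genes=("G0",)):
        index = pd.MultiIndex.from_product([["T0"], list(genes)],
                                           names=["tf", "gene"])
        df = pd.DataFrame(values, index=index)
        return AttributionMatrix(
            values=df, base_values=pd.Series(0.0, index=index)
        )

    def test_single_bound_gene_profile_is_its_shaps(self, regions):
        attr = self._attr({
            "tf_binding:prom_-200:-100": [0.4],
            "tf_binding:prom_-100:0": [0.1],
        })
        profile = positional_profile(attr, regions, "T0", {"G0"})
        assert profile["-200:-100"] == 0.4
        assert profile["-100:0"] == 0.1

    def test_empty_bound_set_gives_nan_row(self, regions):
        attr = self._attr({"tf_binding:prom_-100:0": [0.1]})
        profile = positional_profile(attr, regions, "T0", set())
        assert profile.isna().all()

    def test_shuffled_attributions_average_near_zero(self, regions):
        rng = np.random.default_rng(4)
        n = 400
        genes = [f"G{i}" for i in range(n)]
        attr = self._attr(
            {"tf_binding:prom_-200:-100": rng.normal(0, 1, n)}, genes=genes
        )
        profile = positional_profile(attr, regions, "T0", set(genes))
        assert abs(profile["-200:-100"]) < 2 / np.sqrt(n)


class TestBinGroupTest:
    def _attr_two_groups(self, shift, n=50, seed=0):
        rng = np.random.default_rng(seed)
        genes = [f"R{i}" for i in range(n)] + [f"N{i}" for i in range(n)]
        index = pd.MultiIndex.from_product([["T0"], genes], names=["tf", "gene"])
        vals = np.concatenate([rng.normal(shift, 1, n), rng.normal(0, 1, n)])
        df = pd.DataFrame({"tf_binding:prom_-100:0": vals}, index=index)
        attr = AttributionMatrix(values=df, base_values=pd.Series(0.0, index=index))
        return attr, {f"R{i}" for i in range(n)}, {f"N{i}" for i in range(n)}

    def test_identical_groups_p_near_one(self):
        attr, resp, nonresp = self._attr_two_groups(shift=0.0, seed=1)
        # make the two groups literally identical
        attr.values.iloc[50:, 0] = attr.values.iloc[:50, 0].to_numpy()
        out = bin_group_test(attr, "T0", resp, nonresp)
        assert out["p"].iloc[0] > 0.4

    def test_shifted_group_detected(self):
        hits = 0
        for seed in range(20):
            attr, resp, nonresp = self._attr_two_groups(shift=1.0, seed=seed)
            out = bin_group_test(attr, "T0", resp, nonresp)
            hits += out["p"].iloc[0] < 0.01
        assert hits >= 19  # >= 95% power at +1 SD, n=50/50

    def test_n1_vs_n1_exact_enumeration(self):
        attr, _, _ = self._attr_two_groups(shift=0.0, n=1, seed=2)
        out = bin_group_test(attr, "T0", {"R0"}, {"N0"})
        assert out["p"].iloc[0] in (0.5, 1.0)

    def test_empty_group_gives_nan(self):
        attr, resp, _ = self._attr_two_groups(shift=0.0)
        out = bin_group_test(attr, "T0", resp, set())
        assert out["p"].isna().all()


class TestUpdownImportance:
    @pytest.fixture
    def regions(self):
        return build_regions(
            TssRecord("g", "chr1", 10_000, "+"), [], YEAST_SCHEME, 1_000_000
        )

    def _attr(self, up, down, n=30, seed=0):
        rng = np.random.default_rng(seed)
        genes = [f"G{i}" for i in range(n)]
        index = pd.MultiIndex.from_product([["T0", "T1"], genes],
                                           names=["tf", "gene"])
        df = pd.DataFrame(
            {
                "H3K4me3:prom_-100:0": rng.normal(0, up, 2 * n),
                "H3K4me3:prom_0:100": rng.normal(0, down, 2 * n),
            },
            index=index,
        )
        return AttributionMatrix(values=df, base_values=pd.Series(0.0, index=index))

    def test_nonzero_only_downstream(self, regions):
        attr = self._attr(up=1e-12, down=1.0)
        table, _ = updown_importance(attr, regions, "H3K4me3")
        assert (table["upstream"] < 1e-9).all()
        assert (table["downstream"] > 0.1).all()

    def test_symmetric_attributions_equal(self, regions):
        attr = self._attr(up=1.0, down=1.0)
        attr.values["H3K4me3:prom_0:100"] = attr.values["H3K4me3:prom_-100:0"]
        table, _ = updown_importance(attr, regions, "H3K4me3")
        np.testing.assert_allclose(table["upstream"], table["downstream"])

    def test_missing_class_errors(self, regions):
        attr = self._attr(up=1.0, down=1.0)
        with pytest.raises(ValueError, match="no promoter-bin columns"):
            updown_importance(attr, regions, "H3K27ac")


class TestInputAttributionCorrelation:
    def _pair(self, f, n=300, seed=0):
        rng = np.random.default_rng(seed)
        genes = [f"G{i}" for i in range(n)]
        index = pd.MultiIndex.from_product([["T0"]], names=["tf"])
        index = pd.MultiIndex.from_product([["T0"], genes], names=["tf", "gene"])
        x = rng.normal(size=n)
        matrix = FeatureMatrix(values=pd.DataFrame({"gex_level:gene": x}, index=index))
        attr = AttributionMatrix(
            values=pd.DataFrame({"gex_level:gene": f(x, rng)}, index=index),
            base_values=pd.Series(0.0, index=index),
        )
        return matrix, attr

    def test_monotone_function_gives_plus_one(self):
        matrix, attr = self._pair(lambda x, rng: np.tanh(x) + x**3)
        rho = input_attribution_correlation(attr, matrix, "gex_level:gene")
        assert rho["T0"] == pytest.approx(1.0)

    def test_independent_shap_near_zero(self):
        near_zero = 0
        for seed in range(20):
            matrix, attr = self._pair(
                lambda x, rng: rng.normal(size=len(x)), n=1000, seed=seed
            )
            rho = input_attribution_correlation(attr, matrix, "gex_level:gene")
            near_zero += abs(rho["T0"]) < 0.1
        assert near_zero >= 19

    def test_zero_variance_gives_nan(self):
        matrix, attr = self._pair(lambda x, rng: x)
        matrix.values["gex_level:gene"] = 1.0
        rho = input_attribution_correlation(attr, matrix, "gex_level:gene")
        assert math.isnan(rho["T0"])
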