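import numpy as np
import pandas as pd
import pytest
from scipy import stats

from pertpred.evaluation_null import (
    LsdFit,
    NullModel,
    auprc,
    fit_lsd,
    permutation_null,
    permute_labels,
    pr_by_tf,
    tf_pvalue,
    efficacy_report,
)
from pertpred.features import FeatureMatrix
from pertpred.labels import ResponseLabels
from pertpred.model_cv import Hyperparams, make_tf_folds


class TestAuprc:
    def test_perfect_ranking_is_one(self):
        labels = np.array([0, 0, 0, 1, 1])
        scores = np.array([0.1, 0.2, 0.3, 0.8, 0.9])
        assert auprc(scores, labels) == 1.0

    @pytest.mark.parametrize("prevalence", [0.05, 0.2, 0.5])
    def test_all_equal_scores_give_prevalence(self, prevalence):
        n = 400
        labels = np.zeros(n, dtype=int)
        labels[: int(n * prevalence)] = 1
        scores = np.full(n, 0.5)
        assert auprc(scores, labels) == pytest.approx(prevalence, rel=1e-12)

    def test_random_scores_average_near_prevalence(self):
        """Mean AUPRC under random ranking approaches the response fraction."""
        rng = np.random.default_rng(0)
        n, prevalence = 2000, 0.05
        labels = np.zeros(n, dtype=int)
        labels[: int(n * prevalence)] = 1
        values = [auprc(rng.random(n), labels) for _ in range(200)]
        assert np.mean(values) == pytest.approx(0.05, abs=0.01)

    def test_degenerate_labels_error(self):
        with pytest.raises(ValueError):
            auprc(np.array([0.5, 0.6]), np.array([0, 0]))
        with pytest.raises(ValueError):
            auprc(np.array([0.5, 0.6]), np.array([1, 1]))


class TestPermuteLabels:
    def _labels(self, seed=0):
        rng = np.random.default_rng(seed)
        index = pd.MultiIndex.from_product(
            [["T0", "T1"], [f"G{i}" for i in range(50)]], names=["tf", "gene"]
        )
        y = pd.Series((rng.random(100) < 0.1).astype(int), index=index)
        return ResponseLabels(responsive=y)

    def test_counts_preserved_per_tf(self):
        labels = self._labels()
        perm = permute_labels(labels, seed=1)
        for tf in labels.tfs:
            assert perm.for_tf(tf).sum() == labels.for_tf(tf).sum()

    def test_seed_reproducible(self):
        labels = self._labels()
        p1 = permute_labels(labels, seed=2).responsive
        p2 = permute_labels(labels, seed=2).responsive
        pd.testing.assert_series_equal(p1, p2)

    def test_all_negative_unchanged(self):
        labels = self._labels()
        labels.responsive[:] = 0
        perm = permute_labels(labels, seed=3)
        assert perm.responsive.eq(0).all()


class TestPermutationNull:
    def _problem(self):
        rng = np.random.default_rng(7)
        tfs = ["T0", "T1", "T2"]
        genes = [f"G{i}" for i in range(200)]
        index = pd.MultiIndex.from_product([tfs, genes], names=["tf", "gene"])
        X = pd.DataFrame(
            rng.normal(size=(600, 4)), index=index,
            columns=[f"f{j}:gene" for j in range(4)],
        )
        y = pd.Series((rng.random(600) < 0.1).astype(int), index=index)
        return FeatureMatrix(values=X), ResponseLabels(responsive=y)

    def test_null_mean_near_response_fraction(self):
        matrix, labels = self._problem()
        assignment = make_tf_folds(matrix.tfs, 3, seed=0)
        null = permutation_null(
            matrix, labels, assignment, n_perm=5, seed=0,
            hyperparams=Hyperparams(n_rounds=20, max_depth=3),
        )
        assert set(null.stats.index) == set(labels.tfs)
        for tf in labels.tfs:
            frac = labels.response_fraction(tf)
            se = null.stats.loc[tf, "sd"] / np.sqrt(5)
            assert abs(null.stats.loc[tf, "mean"] - frac) < max(3 * se, 0.05)

    def test_single_permutation_errors(self):
        matrix, labels = self._problem()
        assignment = make_tf_folds(matrix.tfs, 3, seed=0)
        with pytest.raises(ValueError, match="at least 2"):
            permutation_null(matrix, labels, assignment, n_perm=1, seed=0)


class TestLsdFit:
    def _null_on_line(self, fractions, slope, intercept):
        sd = np.exp(intercept + slope * np.log(fractions))
        table = pd.DataFrame(
            {"mean": fractions, "sd": sd},
            index=[f"T{i}" for i in range(len(fractions))],
        )
        return NullModel(stats=table, permutation_count=10, seed=0)

    def test_exact_recovery_on_a_line(self):
        fractions = pd.Series(
            np.linspace(0.02, 0.3, 10), index=[f"T{i}" for i in range(10)]
        )
        null = self._null_on_line(fractions.to_numpy(), 0.8, -1.0)
        fit = fit_lsd(null, fractions)
        assert fit.slope == pytest.approx(0.8, abs=1e-9)
        assert fit.intercept == pytest.approx(-1.0, abs=1e-9)

    def test_conservative_fit_passes_through_quintile_maxima(self):
        rng = np.random.default_rng(1)
        fractions = pd.Series(
            np.linspace(0.02, 0.3, 15), index=[f"T{i}" for i in range(15)]
        )
        sd_line = np.exp(-1.0 + 0.8 * np.log(fractions.to_numpy()))
        sd = sd_line * rng.uniform(0.3, 0.9, 15)  # depressed except maxima
        # plant one dominating outlier per quintile, exactly on a new line
        outliers = [0, 3, 6, 9, 12]
        sd[outliers] = np.exp(-0.5 + 0.6 * np.log(fractions.to_numpy()[outliers]))
        table = pd.DataFrame({"mean": fractions, "sd": sd}, index=fractions.index)
        null = NullModel(stats=table, permutation_count=10, seed=0)
        fit = fit_lsd(null, fractions, variant="conservative_quintile_max")
        assert fit.slope == pytest.approx(0.6, abs=1e-9)
        assert fit.intercept == pytest.approx(-0.5, abs=1e-9)

    def test_all_below_floor_errors(self):
        fractions = pd.Series([0.001, 0.005], index=["T0", "T1"])
        null = self._null_on_line(fractions.to_numpy(), 0.8, -1.0)
        with pytest.raises(ValueError, match="responder floor"):
            fit_lsd(null, fractions)


class TestTfPvalue:
    LSD = LsdFit(slope=0.8, intercept=-1.0)

    def test_real_equal_to_mean_gives_half(self):
        sig = tf_pvalue(0.05, 0.05, null_sd_empirical=0.01, lsd=self.LSD)
        assert sig.p == pytest.approx(0.5, abs=1e-12)

    def test_normal_quantile(self):
        frac = 0.05
        sd = self.LSD.predict_sd(frac)
        sig = tf_pvalue(frac + 1.959964 * sd, frac, 0.01, self.LSD)
        assert sig.p == pytest.approx(0.025, abs=1e-4)

    def test_below_floor_uses_empirical_sd(self):
        sig = tf_pvalue(0.02, 0.005, null_sd_empirical=0.004, lsd=self.LSD,
                        responder_floor=0.01)
        assert sig.sd_source == "empirical"
        assert sig.z == pytest.approx((0.02 - 0.005) / 0.004)

    def test_zero_sd_errors(self):
        with pytest.raises(ValueError, match="SD"):
            tf_pvalue(0.1, 0.005, null_sd_empirical=0.0, lsd=self.LSD)

    def test_monotone_decreasing_in_real_auprc(self):
        ps = [
            tf_pvalue(a, 0.05, 0.01, self.LSD).p
            for a in np.linspace(0.01, 0.6, 25)
        ]
        assert all(p1 > p2 for p1, p2 in zip(ps, ps[1:]))

    def test_pvalues_uniform_under_the_null(self):
        """The permutation -> LSD fit -> normal-tail chain is calibrated.

        Each rep builds a cohort of TFs whose permuted AUPRCs follow the
        modelled null (normal around the response fraction, SD on a log-log
        line plus scatter), fits the LSD model across the cohort, and
        evaluates one independent null draw; 200 such p-values should be
        approximately uniform.
        """
        rng = np.random.default_rng(11)
        slope, intercept = 0.8, -1.0
        pvals = []
        for _ in range(200):
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
            pvals.append(
                tf_pvalue(real, float(fracs[tf]), table.loc[tf, "sd"], lsd).p
            )
        ks = stats.kstest(pvals, "uniform")
        assert ks.pvalue > 0.01

    def test_analytic_mean_is_close_to_empirical_null_mean(self):
        """Random-ranking AUPRC averages near the response fraction.

        The average-precision estimator sits slightly above the prevalence
        at finite n (the permuted mean exceeds the fraction by well under
        0.01 at 2,000 genes), which is why the analytic expectation is a
        usable null centre.
        """
        rng = np.random.default_rng(12)
        n, frac = 2000, 0.05
        y = np.zeros(n, dtype=int)
        y[: int(n * frac)] = 1
        vals = [auprc(rng.random(n), y) for _ in range(100)]
        assert abs(np.mean(vals) - frac) < 0.01


class TestEfficacyReport:
    def test_ratio_and_nan_efficacy_preserved(self):
        index = pd.MultiIndex.from_product(
            [["T0", "T1"], [f"G{i}" for i in range(40)]], names=["tf", "gene"]
        )
        rng = np.random.default_rng(2)
        y = pd.Series((rng.random(80) < 0.2).astype(int), index=index)
        y.loc[("T0", "G0")] = 1
        y.loc[("T1", "G0")] = 1
        labels = ResponseLabels(
            responsive=y, perturbation_efficacy={"T0": 1.7, "T1": float("nan")}
        )
        preds = pd.DataFrame({"prob": rng.random(80), "fold": 0}, index=index)
        pr = pr_by_tf(preds, labels)
        report = efficacy_report(pr, labels)
        assert report.loc["T0", "efficacy"] == 1.7
        assert np.isnan(report.loc["T1", "efficacy"])
        np.testing.assert_allclose(
            report["ratio"], report["auprc"] / report["random_expectation"]
        )
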