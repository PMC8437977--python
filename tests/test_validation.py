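"""Discrimination, screening, bootstrap optimism, and calibration."""

import numpy as np
import pytest
from sklearn.metrics import roc_auc_score

from ntcp_pce import (
    LogisticSpec,
    SyntheticConfig,
    auc,
    bootstrap_optimism,
    collinearity_screen,
    compare_models,
    generate_cohort,
    hosmer_lemeshow,
    probit_ntcp,
    univariate_screen,
)
from ntcp_pce import geud, published
from ntcp_pce.errors import ContractError, DegenerateDataError, DomainError
from ntcp_pce.validation import FixedScoreSpec
from conftest import make_cohort
from tests_util_oracles import pair_counting_auc as _pair_counting_auc


class TestAuc:
    def test_perfect_separation(self):
        a, _ = auc([1, 2, 3, 10, 11, 12], [0, 0, 0, 1, 1, 1], ci=False)
        assert a == 1.0

    def test_hand_examples(self):
        assert auc([1, 2, 3, 4], [0, 0, 1, 1], ci=False)[0] == 1.0
        assert auc([1, 2, 3, 4], [0, 1, 0, 1], ci=False)[0] == 0.75

    def test_agrees_with_pair_counting_and_sklearn(self):
        rng = np.random.default_rng(3)
        for _ in range(30):
            n = rng.integers(6, 50)
            s = rng.choice(np.arange(10.0), size=n)  # heavy ties
            y = rng.integers(0, 2, size=n)
            if y.sum() in (0, n):
                continue
            a, _ = auc(s, y, ci=False)
            assert a == pytest.approx(_pair_counting_auc(s, y), abs=1e-12)
            assert a == pytest.approx(roc_auc_score(y, s), abs=1e-12)

    def test_null_scores_near_half(self):
        rng = np.random.default_rng(5)
        s = rng.normal(size=2000)
        y = rng.integers(0, 2, size=2000)
        a, _ = auc(s, y, ci=False)
        assert a == pytest.approx(0.5, abs=0.03)

    def test_ci_brackets_point(self):
        rng = np.random.default_rng(7)
        s = rng.normal(size=200)
        y = (s + rng.normal(size=200) > 0).astype(int)
        a, (lo, hi) = auc(s, y, n_boot=400, seed=1)
        assert lo <= a <= hi
        assert 0 <= lo < hi <= 1

    def test_single_class_rejected(self):
        with pytest.raises(DegenerateDataError):
            auc([1, 2, 3], [1, 1, 1], ci=False)


class TestUnivariateScreen:
    def test_true_predictor_retained(self):
        rng = np.random.default_rng(11)
        x = rng.normal(size=500)
        p = 1 / (1 + np.exp(-(x - 0.3)))
        y = (rng.uniform(size=500) < p).astype(int)
        cohort = make_cohort({"x": x, "z": rng.normal(size=500)}, y)
        retained, pvals = univariate_screen(cohort, ["x", "z"], "any", p_cut=0.10)
        assert "x" in retained
        assert pvals["x"] < 1e-6

    def test_zero_cut_retains_nothing(self, small_logistic_cohort):
        retained, _ = univariate_screen(small_logistic_cohort, ["mhd"], "any", p_cut=0.0)
        assert retained == []

    def test_noise_retention_near_nominal_rate(self):
        rng = np.random.default_rng(13)
        kept = 0
        reps = 200
        for _ in range(reps):
            x = rng.normal(size=200)
            y = rng.integers(0, 2, size=200)
            if y.sum() in (0, 200):
                continue
            cohort = make_cohort({"x": x}, y)
            retained, _ = univariate_screen(cohort, ["x"], "any", p_cut=0.10)
            kept += bool(retained)
        assert 0.04 <= kept / reps <= 0.17  # nominal 10% under the null


class TestCollinearityScreen:
    def test_duplicated_feature_clusters(self):
        rng = np.random.default_rng(17)
        x = rng.normal(size=300)
        cohort = make_cohort({"a": x, "b": x.copy(), "c": rng.normal(size=300)},
                             np.tile([0, 1], 150))
        clusters = collinearity_screen(cohort, ["a", "b", "c"])
        assert clusters == [{"a", "b"}]

    def test_independent_features_do_not_cluster(self):
        rng = np.random.default_rng(19)
        for _ in range(10):
            feats = {f"g{j}": rng.normal(size=1000) for j in range(4)}
            cohort = make_cohort(feats, np.tile([0, 1], 500))
            assert collinearity_screen(cohort, list(feats)) == []

    def test_constructed_correlation_clusters(self):
        rng = np.random.default_rng(23)
        x = rng.normal(size=1000)
        y = 0.9 * x + rng.normal(scale=0.9 * np.sqrt(1 / 0.81 - 1), size=1000)
        cohort = make_cohort({"x": x, "y": y}, np.tile([0, 1], 500))
        assert collinearity_screen(cohort, ["x", "y"]) == [{"x", "y"}]

    def test_constant_feature_excluded_with_warning(self):
        cohort = make_cohort({"k": np.ones(40), "x": np.arange(40.0)},
                             np.tile([0, 1], 20))
        with pytest.warns(UserWarning):
            clusters = collinearity_screen(cohort, ["k", "x"])
        assert clusters == []


class TestBootstrapOptimism:
    def test_fixed_score_model_has_negligible_optimism(self, small_logistic_cohort):
        # nothing is estimated, so optimism is zero in expectation; the
        # residual is pure resampling noise of the AUC estimator
        spec = FixedScoreSpec(lambda c: c.mhd_array(), "any")
        out = bootstrap_optimism(small_logistic_cohort, spec, "any", B=200, seed=1)
        assert out["mean_optimism"] == pytest.approx(0.0, abs=0.01)
        assert out["adjusted_auc"] == pytest.approx(out["apparent_auc"], abs=0.01)

    def test_well_specified_model_has_small_optimism(self):
        cfg = SyntheticConfig(n_patients=1000, seed=29, with_dvh=False)
        cohort = generate_cohort(cfg)
        out = bootstrap_optimism(cohort, LogisticSpec(["mhd"], "any"), "any",
                                 B=200, seed=2)
        assert abs(out["mean_optimism"]) < 0.01

    def test_invariant_to_monotone_score_rescaling(self, small_logistic_cohort):
        spec_raw = FixedScoreSpec(lambda c: c.mhd_array(), "any")
        spec_mono = FixedScoreSpec(lambda c: np.log1p(c.mhd_array()) ** 3, "any")
        a = bootstrap_optimism(small_logistic_cohort, spec_raw, "any", B=40, seed=3)
        b = bootstrap_optimism(small_logistic_cohort, spec_mono, "any", B=40, seed=3)
        assert a["apparent_auc"] == pytest.approx(b["apparent_auc"], abs=1e-12)
        assert a["mean_optimism"] == pytest.approx(b["mean_optimism"], abs=1e-12)


class TestHosmerLemeshow:
    def test_exactly_calibrated_groups_give_zero(self):
        p = np.array([0.2] * 10 + [0.8] * 10)
        y = np.array([1, 1] + [0] * 8 + [1] * 8 + [0, 0])
        chi2, _, g = hosmer_lemeshow(p, y, g=4)
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert g == 2  # ties keep each probability level in one group

    def test_statistic_non_negative_and_grows_with_miscalibration(self):
        rng = np.random.default_rng(31)
        p = rng.uniform(0.1, 0.9, size=500)
        y_cal = (rng.uniform(size=500) < p).astype(int)
        y_bad = (rng.uniform(size=500) < np.clip(p + 0.25, 0, 0.99)).astype(int)
        chi_cal, _, _ = hosmer_lemeshow(p, y_cal, g=10)
        chi_bad, _, _ = hosmer_lemeshow(p, y_bad, g=10)
        assert 0 <= chi_cal < chi_bad

    def test_p_uniform_under_calibrated_null(self):
        # predictions are the true probabilities (nothing estimated), so the
        # statistic is approximately chi-square with g degrees of freedom
        from scipy.stats import kstest

        rng = np.random.default_rng(37)
        pvals = []
        for _ in range(200):
            p = rng.uniform(0.05, 0.95, size=1000)
            y = (rng.uniform(size=1000) < p).astype(int)
            _, pv, _ = hosmer_lemeshow(p, y, g=10, df=10)
            pvals.append(pv)
        assert kstest(pvals, "uniform").pvalue > 0.005

    def test_rejects_bad_inputs(self):
        with pytest.raises(ContractError):
            hosmer_lemeshow([0.5, 0.5], [0, 1], g=2)
        with pytest.raises(DomainError):
            hosmer_lemeshow([0.0, 0.5, 0.7], [0, 1, 0], g=3)


class TestCompareModels:
    def test_identity(self):
        p = np.linspace(0.1, 0.9, 20)
        slope, intercept, r2 = compare_models(p, p)
        assert (slope, intercept, r2) == (pytest.approx(1.0), pytest.approx(0.0),
                                          pytest.approx(1.0))

    def test_anticorrelated_slope_negative(self):
        p = np.linspace(0.1, 0.9, 20)
        slope, _, _ = compare_models(p, 1 - p)
        assert slope < 0

    def test_mhd_and_lkb_agree_on_concentrated_dvhs(self):
        # near-uniform DVHs make gEUD ~ MHD, so the two published A-PCE probit
        # models order patients identically and agree almost linearly
        cfg = SyntheticConfig(n_patients=150, seed=41, dvh_heterogeneity=0.5)
        cohort = generate_cohort(cfg)
        mhd_preds = probit_ntcp(cohort.mhd_array(), published.APCE_MHD_PROBIT)
        geuds = np.array([geud(p.dvh, published.APCE_LKB.n) for p in cohort])
        lkb_preds = probit_ntcp(geuds, published.APCE_LKB)
        _, _, r2 = compare_models(mhd_preds, lkb_preds)
        assert r2 > 0.9

    def test_zero_variance_rejected(self):
        with pytest.raises(DomainError):
            compare_models([0.5, 0.5, 0.5], [0.1, 0.5, 0.9])


class TestWholePipelineAucBand:
    def test_apparent_auc_within_published_band(self):
        # cohorts drawn from the published A-PCE logistic truth at n = 229:
        # apparent AUC of MHD should fall in the widened printed CI band
        inside = 0
        for rep in range(50):
            cfg = SyntheticConfig(n_patients=229, seed=600 + rep, with_dvh=False)
            cohort = generate_cohort(cfg)
            a, _ = auc(cohort.mhd_array(), cohort.outcome_array("any"), ci=False)
            inside += 0.63 <= a <= 0.79
        assert inside >= 45
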