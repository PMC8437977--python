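"""Maximum-likelihood fitting: LKB optimiser, logistic regression, stepwise."""

import numpy as np
import pytest

from ntcp_pce import (
    LKBParameters,
    SyntheticConfig,
    binary_log_likelihood,
    fit_lkb,
    fit_logistic,
    forward_stepwise,
    generate_cohort,
    probit_ntcp,
)
from ntcp_pce import published
from ntcp_pce.errors import ContractError, DegenerateDataError, SeparationError
from conftest import make_cohort


class TestBinaryLogLikelihood:
    def test_single_coin_flip(self):
        assert binary_log_likelihood([0.5], [1]) == pytest.approx(-np.log(2), abs=1e-9)

    def test_perfect_prediction_limit(self):
        ll = binary_log_likelihood([1.0, 1.0, 0.0], [1, 1, 0])
        assert -1e-6 <= ll <= 0.0

    def test_hand_sum(self):
        ll = binary_log_likelihood([0.2, 0.5, 0.9], [0, 1, 1])
        assert ll == pytest.approx(np.log(0.8) + np.log(0.5) + np.log(0.9), abs=1e-9)

    def test_length_mismatch(self):
        with pytest.raises(ContractError):
            binary_log_likelihood([0.5, 0.5], [1])


class TestFitLkb:
    def test_mhd_reduction_recovers_probit_truth(self):
        # outcomes drawn from the published MHD probit model; fix_n = 1 fit
        cfg = SyntheticConfig(n_patients=1000, seed=11, with_dvh=False,
                              truth_any=published.APCE_MHD_PROBIT)
        cohort = generate_cohort(cfg)
        res = fit_lkb(cohort, "any", fix_n=1.0, seed=1)
        assert res.params.n == 1.0
        assert res.params.td50 == pytest.approx(34.3, abs=4.0)
        assert res.params.m == pytest.approx(0.75, abs=0.25)
        assert res.log_likelihood <= 0.0

    def test_free_fit_recovers_dvh_truth(self):
        # truth (n=0.4, m=0.3, TD50=50) on DVH cohorts; median of 5 replicates
        truth = LKBParameters(n=0.4, m=0.3, td50=50.0)
        td50s, ms = [], []
        for rep in range(5):
            cfg = SyntheticConfig(n_patients=500, seed=300 + rep, truth_any=truth,
                                  dvh_bin_width=0.5)
            cohort = generate_cohort(cfg)
            res = fit_lkb(cohort, "any", seed=1)
            td50s.append(res.params.td50)
            ms.append(res.params.m)
        assert np.median(td50s) == pytest.approx(50.0, abs=5.0)
        assert np.median(ms) == pytest.approx(0.3, abs=0.1)

    def test_optimum_never_beaten_by_coarse_grid(self):
        cfg = SyntheticConfig(n_patients=150, seed=7, dvh_bin_width=0.5)
        cohort = generate_cohort(cfg)
        res = fit_lkb(cohort, "any", seed=1)
        assert res.log_likelihood >= res.extras["grid_best_ll"] - 1e-9

    def test_profile_property_fixing_n_at_optimum(self):
        cfg = SyntheticConfig(n_patients=200, seed=9, dvh_bin_width=0.5)
        cohort = generate_cohort(cfg)
        free = fit_lkb(cohort, "any", seed=1)
        prof = fit_lkb(cohort, "any", fix_n=free.params.n, seed=1)
        assert prof.params.m == pytest.approx(free.params.m, abs=1e-3)
        assert prof.params.td50 == pytest.approx(free.params.td50, abs=1e-3)

    def test_uniform_dose_cohort_has_flat_n_direction(self):
        # every DVH a single bin: gEUD is independent of n, so the fit must
        # succeed and report a near-zero gradient in the n direction
        cfg = SyntheticConfig(n_patients=120, seed=13, dvh_heterogeneity=0.0)
        cohort = generate_cohort(cfg)
        res = fit_lkb(cohort, "any", seed=1)
        n_idx = res.extras["free"].index("n")
        assert abs(res.gradient[n_idx]) < 1e-3

    def test_degenerate_cohort_rejected(self):
        y = np.ones(20, dtype=int)
        cohort = make_cohort({"mhd": np.linspace(5, 50, 20)}, y)
        with pytest.raises(DegenerateDataError):
            fit_lkb(cohort, "any", fix_n=1.0)


class TestFitLogistic:
    def test_recovers_published_truth_coefficient(self):
        coefs = []
        for rep in range(5):
            cfg = SyntheticConfig(n_patients=2000, seed=500 + rep, with_dvh=False,
                                  truth_any=published.APCE_LOGISTIC)
            cohort = generate_cohort(cfg)
            res = fit_logistic(cohort, ["mhd"], "any")
            coefs.append(res.params.coefficients["mhd"])
        assert np.median(coefs) == pytest.approx(0.073, abs=0.015)

    def test_odds_ratio_pairing(self):
        assert round(float(np.exp(0.073)), 3) == 1.076

    def test_null_feature_has_near_zero_coefficient(self):
        rng = np.random.default_rng(21)
        coefs = []
        for _ in range(3):
            x = rng.normal(size=5000)
            y = (rng.uniform(size=5000) < 0.3).astype(int)
            cohort = make_cohort({"noise": x}, y)
            coefs.append(fit_logistic(cohort, ["noise"], "any").params.coefficients["noise"])
        assert abs(np.mean(coefs)) < 0.05

    def test_wald_ci_brackets_estimate(self, small_logistic_cohort):
        res = fit_logistic(small_logistic_cohort, ["mhd"], "any")
        lo, hi = res.params.wald_ci()["mhd"]
        assert lo < res.params.odds_ratios()["mhd"] < hi

    def test_perfect_separation_flagged(self):
        x = np.linspace(-2, 2, 40)
        y = (x > 0).astype(int)
        cohort = make_cohort({"x": x}, y)
        with pytest.raises(SeparationError):
            fit_logistic(cohort, ["x"], "any")

    def test_constant_feature_rejected(self):
        y = np.tile([0, 1], 10)
        cohort = make_cohort({"c": np.ones(20)}, y)
        with pytest.raises(DegenerateDataError):
            fit_logistic(cohort, ["c"], "any")


def _noise_cohort(rng, n, n_noise, signal_beta=0.0):
    feats = {f"f{j}": rng.normal(size=n) for j in range(n_noise)}
    eta = -0.5 + signal_beta * feats.get("f0", 0.0)
    p = 1 / (1 + np.exp(-eta))
    y = (rng.uniform(size=n) < p).astype(int)
    return make_cohort(feats, y)


class TestForwardStepwise:
    def test_single_strong_predictor_selected(self):
        hits = 0
        rng = np.random.default_rng(31)
        for _ in range(20):
            cohort = _noise_cohort(rng, 1000, 4, signal_beta=1.0)
            res = forward_stepwise(cohort, ["f0", "f1", "f2", "f3"], "any", alpha=0.05)
            if res.selected_features and res.selected_features[0] == "f0":
                hits += 1
        assert hits >= 18  # strong log-OR 1.0 signal: near-certain first entry

    def test_noise_entry_rate_controlled(self):
        rng = np.random.default_rng(37)
        entries = {f"f{j}": 0 for j in range(4)}
        reps = 60
        for _ in range(reps):
            cohort = _noise_cohort(rng, 1000, 4)
            res = forward_stepwise(cohort, list(entries), "any", alpha=0.05)
            for f in res.selected_features:
                entries[f] += 1
        for f, k in entries.items():
            assert k / reps <= 0.10, f"noise feature {f} entered too often"

    def test_alpha_one_admits_all_candidates_by_gain(self):
        rng = np.random.default_rng(41)
        cohort = _noise_cohort(rng, 400, 3, signal_beta=0.8)
        res = forward_stepwise(cohort, ["f0", "f1", "f2"], "any", alpha=1.0)
        assert set(res.selected_features) == {"f0", "f1", "f2"}
        assert res.selected_features[0] == "f0"  # largest LRT gain first

    def test_empty_candidates_returns_intercept_only(self, small_logistic_cohort):
        res = forward_stepwise(small_logistic_cohort, [], "any")
        assert res.selected_features == []
        y = small_logistic_cohort.outcome_array("any")
        p = y.mean()
        assert res.params.intercept == pytest.approx(np.log(p / (1 - p)), abs=1e-9)
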