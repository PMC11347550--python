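"""Evaluation statistics: worked examples, properties, reference agreement."""

import numpy as np
import pytest
from scipy.stats import mannwhitneyu

from ctprog.evalstats import (
    calibration_curve,
    compare_stratifiers,
    evaluate_scores,
    harrell_c,
    km_estimate,
    logrank_and_hr,
    nomogram,
    stratify,
    time_dependent_auc,
)
from ctprog.clinical import fit_cox
from ctprog.phantom import simulate_survival


# ---------------------------------------------------------------------------
# Harrell C
# ---------------------------------------------------------------------------

class TestHarrellC:
    def test_perfect_ranking(self):
        c, _, ci = harrell_c([3, 2, 1], [1, 2, 3], [1, 1, 1])
        assert c == 1.0
        assert ci[0] <= c <= ci[1]

    def test_anti_ranking(self):
        c, _, _ = harrell_c([1, 2, 3], [1, 2, 3], [1, 1, 1])
        assert c == 0.0

    def test_tie_gets_half_credit(self):
        # pairs: (1,2) tied scores -> 0.5; (1,3) and (2,3) concordant
        c, _, _ = harrell_c([2, 2, 1], [1, 2, 3], [1, 1, 0])
        assert c == pytest.approx(2.5 / 3)

    def test_negating_scores_flips_c(self, rng):
        s = rng.normal(size=30)
        t = rng.uniform(1, 100, 30)
        e = (rng.random(30) < 0.7).astype(int)
        e[0] = 1
        c, _, _ = harrell_c(s, t, e)
        c_neg, _, _ = harrell_c(-s, t, e)
        assert c_neg == pytest.approx(1.0 - c, abs=1e-12)

    def test_no_comparable_pairs_rejected(self):
        with pytest.raises(ValueError):
            harrell_c([1.0, 2.0], [5.0, 5.0], [0, 1])


# ---------------------------------------------------------------------------
# time-dependent AUC
# ---------------------------------------------------------------------------

class TestTimeDependentAUC:
    def test_equals_mann_whitney_without_censoring(self, rng):
        n = 60
        s = rng.normal(size=n)
        t = rng.exponential(50, n)
        e = np.ones(n, dtype=int)
        h = float(np.median(t))
        label = (t <= h).astype(int)
        mw = mannwhitneyu(s[label == 1], s[label == 0]).statistic
        mw /= label.sum() * (n - label.sum())
        assert time_dependent_auc(s, t, e, h) == pytest.approx(mw, abs=1e-12)

    def test_separated_scores_reach_one(self):
        t = np.array([1.0, 2.0, 10.0, 11.0])
        e = np.array([1, 1, 0, 0])
        s = np.array([5.0, 4.0, 1.0, 0.0])
        assert time_dependent_auc(s, t, e, 5.0) == 1.0

    def test_uninformative_scores_near_half(self, rng):
        n = 1000
        t, e = simulate_survival(np.zeros(n), 1 / 300.0, 1800.0, rng)
        s = rng.normal(size=n)
        auc = time_dependent_auc(s, t, e, 365.0)
        assert abs(auc - 0.5) < 0.05

    def test_error_paths(self):
        with pytest.raises(ValueError):
            time_dependent_auc([1, 2], [1, 2], [1, 1], 10.0)  # horizon outside
        with pytest.raises(ValueError):
            time_dependent_auc([1, 2], [1.0, 2.0], [0, 0], 1.5)  # no cases


# ---------------------------------------------------------------------------
# Kaplan-Meier
# ---------------------------------------------------------------------------

class TestKM:
    def test_all_events_product_limit(self):
        km = km_estimate([1, 2, 3, 4], [1, 1, 1, 1])
        assert np.allclose(km.survival, [0.75, 0.5, 0.25, 0.0])
        assert km.median == 2.0

    def test_single_censored_patient(self):
        km = km_estimate([5.0], [0])
        assert km.survival_at(10.0) == 1.0
        assert km.median is None

    def test_censoring_shrinks_risk_set(self):
        # after the censoring at t=2, only one subject remains at risk at t=3,
        # so its event drops the product-limit curve to zero (lifelines agrees)
        km = km_estimate([1, 2, 3], [1, 0, 1])
        assert km.survival_at(1.0) == pytest.approx(2 / 3)
        assert km.survival_at(2.5) == pytest.approx(2 / 3)
        assert km.survival_at(3.0) == pytest.approx(0.0)

    def test_no_censoring_equals_empirical_survival(self, rng):
        t = rng.uniform(1, 100, 50)
        km = km_estimate(t, np.ones(50, int))
        for q in (10.0, 40.0, 90.0):
            assert km.survival_at(q) == pytest.approx(np.mean(t > q), abs=1e-12)


# ---------------------------------------------------------------------------
# log-rank / HR
# ---------------------------------------------------------------------------

class TestLogrankHR:
    def test_identical_groups_are_null(self):
        t = np.array([1, 2, 3, 4, 1, 2, 3, 4], dtype=float)
        e = np.array([1, 1, 0, 1, 1, 1, 0, 1])
        g = np.array(["low"] * 4 + ["high"] * 4)
        p, hr, _ = logrank_and_hr(t, e, g)
        assert p == pytest.approx(1.0)
        assert hr == pytest.approx(1.0, abs=1e-6)

    def test_fully_separated_groups(self):
        # every high-risk subject fails before any low-risk one: the log-rank
        # p is tiny and the HR estimate diverges upward (reported as inf)
        t = np.concatenate([np.arange(1.0, 11.0), np.arange(20.0, 30.0)])
        e = np.ones(20, dtype=int)
        g = np.array(["high"] * 10 + ["low"] * 10)
        p, hr, ci = logrank_and_hr(t, e, g)
        assert p < 0.01
        assert hr > 1
        assert ci[0] <= hr <= ci[1]

    def test_matches_lifelines(self, rng):
        from lifelines.statistics import logrank_test

        t = rng.exponential(100, 40)
        e = (rng.random(40) < 0.8).astype(int)
        e[:2] = 1
        g = np.where(rng.random(40) < 0.5, "high", "low")
        p, _, _ = logrank_and_hr(t, e, g)
        ref = logrank_test(t[g == "high"], t[g == "low"],
                           e[g == "high"], e[g == "low"])
        assert p == pytest.approx(ref.p_value, abs=1e-10)

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            logrank_and_hr([1.0, 2.0], [1, 1], ["low", "low"])


# ---------------------------------------------------------------------------
# stratification
# ---------------------------------------------------------------------------

class TestStratify:
    def test_score_at_cutoff_is_low_risk(self):
        assert stratify([0.66], 0.66)[0] == "low"
        assert stratify([0.661], 0.66)[0] == "high"

    def test_all_below_cutoff(self):
        assert (stratify([0.1, 0.2], 0.66) == "low").all()

    def test_median_cutoff_splits_odd_cohort(self, rng):
        s = rng.normal(size=31)  # distinct with prob 1
        labels = stratify(s, float(np.median(s)))
        assert (labels == "high").sum() == 15


# ---------------------------------------------------------------------------
# nomogram
# ---------------------------------------------------------------------------

class TestNomogram:
    @pytest.fixture()
    def fitted(self, rng):
        import pandas as pd

        n = 120
        X = pd.DataFrame({"a": rng.normal(size=n), "b": rng.binomial(1, 0.4, n)})
        t, e = simulate_survival(0.8 * X.a.to_numpy() - 0.5 * X.b.to_numpy(),
                                 1 / 300.0, 1800.0, rng)
        return fit_cox(X, t, e), X

    def test_single_covariate_spans_0_to_100(self, fitted, rng):
        import pandas as pd

        fit, X = fitted
        single = fit_cox(X[["a"]], *simulate_survival(
            0.8 * X.a.to_numpy(), 1 / 300.0, 1800.0, np.random.default_rng(1)))
        nom = nomogram(single, [365.0], X[["a"]])
        pts = [nom.points({"a": v}) for v in (X.a.min(), X.a.max())]
        assert min(pts) == pytest.approx(0.0, abs=1e-9)
        assert max(pts) == pytest.approx(100.0, abs=1e-9)

    def test_baseline_patient_gets_baseline_survival(self, fitted):
        fit, X = fitted
        nom = nomogram(fit, [365.0], X)
        lp0_points = -nom.lp_offset / nom.unit  # total points where lp == 0
        s = nom.survival_from_points(lp0_points, 365.0)
        assert s == pytest.approx(np.exp(-fit.cumhaz_at(365.0)), abs=1e-9)

    def test_point_path_equals_direct_cox_prediction(self, fitted):
        fit, X = fitted
        nom = nomogram(fit, [365.0, 730.0], X)
        for i in range(0, len(X), 17):
            row = X.iloc[i]
            lp = float(fit.linear_predictor(row.to_frame().T)[0])
            direct = float(fit.survival(365.0, lp))
            via_points = nom.survival_from_points(nom.points(row), 365.0)
            assert via_points == pytest.approx(direct, abs=1e-6)

    def test_horizon_beyond_support_rejected(self, fitted):
        fit, X = fitted
        with pytest.raises(ValueError):
            nomogram(fit, [1e7], X)


# ---------------------------------------------------------------------------
# calibration
# ---------------------------------------------------------------------------

class TestCalibration:
    def test_true_model_predictions_are_calibrated(self, rng):
        n = 1000
        lp = rng.normal(scale=0.8, size=n)
        rate = 1 / 300.0
        t, e = simulate_survival(lp, rate, 1800.0, rng)
        h = 365.0
        pred = np.exp(-rate * h * np.exp(lp))  # true survival probabilities
        bins = calibration_curve(pred, t, e, h, n_bins=3)
        for b in bins:
            assert abs(b["mean_predicted"] - b["km_observed"]) < 0.1

    def test_constant_predictions_collapse_to_overall_km(self, rng):
        n = 60
        t, e = simulate_survival(np.zeros(n), 1 / 300.0, 1800.0, rng)
        bins = calibration_curve(np.full(n, 0.7), t, e, 365.0, n_bins=3)
        assert len(bins) == 1
        overall = km_estimate(t, e).survival_at(365.0)
        assert bins[0]["km_observed"] == pytest.approx(overall)

    def test_anticalibrated_predictions_slope_negative(self, rng):
        n = 600
        lp = rng.normal(scale=1.2, size=n)
        rate = 1 / 300.0
        t, e = simulate_survival(lp, rate, 1800.0, rng)
        h = 365.0
        pred = 1.0 - np.exp(-rate * h * np.exp(lp))
        bins = calibration_curve(pred, t, e, h, n_bins=3)
        x = [b["mean_predicted"] for b in bins]
        y = [b["km_observed"] for b in bins]
        slope = np.polyfit(x, y, 1)[0]
        assert slope < 0


# ---------------------------------------------------------------------------
# stratifier comparison + bundle
# ---------------------------------------------------------------------------

class TestCompareStratifiers:
    def test_identical_groupings_identical_results(self, rng):
        n = 60
        s = rng.normal(size=n)
        t, e = simulate_survival(s, 1 / 300.0, 1800.0, rng)
        cutoff = float(np.median(s))
        prog = (s > cutoff).astype(int)
        out = compare_stratifiers(s, cutoff, prog, t, e)
        assert out["model"]["hr"] == pytest.approx(out["size_based"]["hr"])
        assert out["model"]["p"] == pytest.approx(out["size_based"]["p"])


def test_evaluate_scores_bundle(rng):
    n = 100
    s = rng.normal(size=n)
    t, e = simulate_survival(1.2 * s, 1 / 300.0, 1800.0, rng)
    ev = evaluate_scores(s, t, e, [365.0], float(np.median(s)))
    assert 0.5 < ev.c_index <= 1.0
    assert ev.c_index_ci[0] <= ev.c_index <= ev.c_index_ci[1]
    assert 0.0 <= ev.auc_t[365.0] <= 1.0
    assert ev.hr > 1.0
    assert set(np.unique(ev.group_labels)) == {"low", "high"}
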