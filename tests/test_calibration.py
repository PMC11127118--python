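"""Per-integer scan, projection, thresholds, concordance, net benefit."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit, logit

from raicd.calibration import (
    CalibrationTable,
    ProjectionModel,
    ScoreCalibration,
    build_calibration_table,
    c_statistic,
    convergent_validity,
    derive_thresholds,
    net_benefit,
    outcomes_by_category,
    projected_mortality_curve,
    threshold_scan,
)
from raicd.errors import CalibrationError


def _random_cohort(rng, n):
    scores = rng.integers(0, 60, n)
    p = expit(-5 + 0.1 * scores)
    deaths = rng.random(n) < p
    weights = rng.uniform(0.5, 3.0, n)
    return scores, deaths, weights


def _oracle_scan(scores, deaths, weights, kmax):
    """Brute-force per-threshold confusion matrix, straight from definitions."""
    rows = []
    W = weights.sum()
    D = weights[deaths].sum()
    for k in range(kmax + 1):
        call = scores >= k
        tp = weights[call & deaths].sum()
        fp = weights[call & ~deaths].sum()
        fn = D - tp
        tn = (W - D) - fp
        f1 = 2 * tp / (2 * tp + fp + fn) if 2 * tp + fp + fn > 0 else np.nan
        prod = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
        mcc = (tp * tn - fp * fn) / np.sqrt(prod) if prod > 1e-12 else np.nan
        rows.append((k, tp, fp, fn, tn,
                     tp / D if D else np.nan, tn / (W - D) if W - D else np.nan,
                     f1, mcc,
                     weights[scores <= k].sum() / W))
    return rows


def _oracle_concordance(scores, deaths, weights):
    """All-pairs weighted concordance, O(n^2)."""
    di = np.flatnonzero(deaths)
    si = np.flatnonzero(~deaths)
    num = den = 0.0
    for i in di:
        for j in si:
            w = weights[i] * weights[j]
            den += w
            if scores[i] > scores[j]:
                num += w
            elif scores[i] == scores[j]:
                num += 0.5 * w
    return num / den


class TestThresholdScan:
    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(21)
        scores, deaths, weights = _random_cohort(rng, 150)
        kmax = int(scores.max())
        tab = threshold_scan(scores, deaths, weights, max_score=kmax)
        for row in _oracle_scan(scores, deaths, weights, kmax):
            k, tp, fp, fn, tn, sens, spec, f1, mcc, cum = row
            r = tab.iloc[k]
            np.testing.assert_allclose(
                [r.tp, r.fp, r.fn, r.tn], [tp, fp, fn, tn], atol=1e-9
            )
            for ours, oracle in ((r.sensitivity, sens), (r.specificity, spec),
                                 (r.f1, f1), (r.mcc, mcc), (r.cum_proportion, cum)):
                if np.isnan(oracle):
                    assert np.isnan(ours) or abs(ours) < 1e-6
                else:
                    assert ours == pytest.approx(oracle, abs=1e-6)

    def test_worked_confusion_matrix_values(self):
        # TP=8 FP=2 FN=2 TN=88 at k=1 with unit weights
        scores = np.repeat([1, 1, 0, 0], [8, 2, 2, 88])
        deaths = np.repeat([True, False, True, False], [8, 2, 2, 88])
        tab = threshold_scan(scores, deaths)
        r = tab.iloc[1]
        assert (r.tp, r.fp, r.fn, r.tn) == (8, 2, 2, 88)
        assert r.f1 == pytest.approx(0.8)
        assert r.mcc == pytest.approx(700 / 900)

    def test_perfect_classifier_scores_one(self):
        scores = np.repeat([10, 0], [5, 95])
        deaths = np.repeat([True, False], [5, 95])
        r = threshold_scan(scores, deaths).iloc[10]
        assert r.f1 == pytest.approx(1.0) and r.mcc == pytest.approx(1.0)

    def test_monotone_invariants_and_undefined_ratios(self):
        rng = np.random.default_rng(22)
        scores, deaths, weights = _random_cohort(rng, 400)
        tab = threshold_scan(scores, deaths, weights, max_score=70)
        sens = tab["sensitivity"].to_numpy()
        spec = tab["specificity"].to_numpy()
        assert (np.diff(sens) <= 1e-12).all()
        assert (np.diff(spec) >= -1e-12).all()
        cum = tab["cum_proportion"].to_numpy()
        assert (np.diff(cum) >= -1e-12).all() and cum[-1] == pytest.approx(1.0)
        total = tab[["tp", "fp", "fn", "tn"]].sum(axis=1)
        np.testing.assert_allclose(total, weights.sum())
        # beyond max observed score there are no positive calls: PPV undefined
        assert np.isnan(tab["ppv"].iloc[-1]) or tab["n_at_k"].iloc[-1] > 0


class TestProjection:
    def test_closed_form_evaluation(self):
        pm = ProjectionModel(intercept=-6.0, slope=0.12)
        assert pm.predict(30) == pytest.approx(expit(-2.4), abs=1e-12)
        assert pm.predict(30) == pytest.approx(0.0832, abs=5e-4)

    def test_flat_curve_when_score_uninformative(self):
        rng = np.random.default_rng(23)
        n = 20_000
        scores = rng.integers(0, 50, n)
        deaths = rng.random(n) < 0.05  # independent of score
        pm = projected_mortality_curve(scores, deaths)
        m = deaths.mean()
        assert pm.predict(0) == pytest.approx(m, abs=0.01)
        assert pm.predict(49) == pytest.approx(m, abs=0.01)

    def test_positive_slope_gives_strictly_increasing_curve(self):
        rng = np.random.default_rng(24)
        scores, deaths, weights = _random_cohort(rng, 5000)
        pm = projected_mortality_curve(scores, deaths, weights)
        assert pm.slope > 0
        curve = pm.predict(np.arange(0, 60))
        assert (np.diff(curve) > 0).all()

    def test_single_class_rejected(self):
        with pytest.raises(CalibrationError):
            projected_mortality_curve([1, 2, 3], [False, False, False])


class TestDeriveThresholds:
    def _table(self, pm, m_bar, kmax=81):
        tab = pd.DataFrame({"k": np.arange(kmax + 1)})
        tab["f1"] = 0.33
        tab["mcc"] = 0.26
        tab["observed_mortality"] = pm.predict(tab["k"].to_numpy())
        return CalibrationTable(table=tab, overall_mortality=m_bar, projection=pm)

    def test_closed_form_rule_inversion(self):
        # p(k) = expit(-6 + 0.12 k), overall mortality 2.5%
        pm = ProjectionModel(intercept=-6.0, slope=0.12)
        d = derive_thresholds(self._table(pm, 0.025))
        assert d.frail_threshold == 26
        assert d.very_frail_threshold == 32
        assert d.robust_bound == 19
        assert d.thresholds.robust_below == 20
        assert d.thresholds.normal_upper == 25
        assert d.thresholds.frail_upper == 31

    def test_rule_unsatisfiable_raises(self):
        pm = ProjectionModel(intercept=-6.0, slope=0.12)
        with pytest.raises(CalibrationError):
            derive_thresholds(self._table(pm, 0.025, kmax=10))

    def test_non_positive_slope_rejected(self):
        pm = ProjectionModel(intercept=-3.0, slope=0.0)
        with pytest.raises(CalibrationError):
            derive_thresholds(self._table(pm, 0.025))

    def test_weight_rescaling_invariance(self):
        rng = np.random.default_rng(25)
        scores, deaths, weights = _random_cohort(rng, 20_000)
        t1 = build_calibration_table(scores, deaths, weights, max_score=70)
        t2 = build_calibration_table(scores, deaths, weights * 7.3, max_score=70)
        d1, d2 = derive_thresholds(t1), derive_thresholds(t2)
        assert (d1.frail_threshold, d1.very_frail_threshold, d1.robust_bound) == (
            d2.frail_threshold, d2.very_frail_threshold, d2.robust_bound
        )


class TestCStatistic:
    def test_hand_computed_pairs(self):
        # deaths scored {3,1}, survivors {2,0}: 3 of 4 pairs concordant
        scores = [3, 1, 2, 0]
        deaths = [True, True, False, False]
        assert c_statistic(scores, deaths, n_boot=0).estimate == pytest.approx(0.75)

    def test_perfect_and_constant_scores(self):
        deaths = [True] * 5 + [False] * 5
        assert c_statistic([1] * 5 + [0] * 5, deaths, n_boot=0).estimate == 1.0
        assert c_statistic([4] * 10, deaths, n_boot=0).estimate == 0.5

    def test_matches_all_pairs_oracle_weighted(self):
        rng = np.random.default_rng(26)
        for _ in range(5):
            scores, deaths, weights = _random_cohort(rng, 120)
            if deaths.all() or not deaths.any():
                continue
            ours = c_statistic(scores, deaths, weights, n_boot=0).estimate
            assert ours == pytest.approx(
                _oracle_concordance(scores, deaths, weights), abs=1e-12
            )

    def test_matches_sklearn_auc(self):
        sklearn = pytest.importorskip("sklearn.metrics")
        rng = np.random.default_rng(27)
        scores, deaths, weights = _random_cohort(rng, 500)
        ours = c_statistic(scores, deaths, weights, n_boot=0).estimate
        ref = sklearn.roc_auc_score(deaths, scores, sample_weight=weights)
        assert ours == pytest.approx(ref, abs=1e-10)

    def test_bootstrap_ci_brackets_estimate_and_is_seeded(self):
        rng = np.random.default_rng(28)
        scores, deaths, weights = _random_cohort(rng, 400)
        r1 = c_statistic(scores, deaths, weights, n_boot=50, seed=5)
        r2 = c_statistic(scores, deaths, weights, n_boot=50, seed=5)
        assert (r1.ci_low, r1.ci_high) == (r2.ci_low, r2.ci_high)
        assert r1.ci_low <= r1.estimate <= r1.ci_high

    def test_single_class_rejected(self):
        with pytest.raises(CalibrationError):
            c_statistic([1, 2], [True, True])


class TestNetBenefit:
    def test_direct_formula(self):
        calls = np.repeat([True, False], [10, 90])
        deaths = np.repeat([True, False, True, False], [8, 2, 2, 88])
        nb = net_benefit(calls, deaths, 0.5)
        assert nb.net_benefit == pytest.approx(0.08 - 0.02)

    def test_no_positive_calls_gives_zero(self):
        nb = net_benefit([False] * 10, [True] * 2 + [False] * 8, 0.3)
        assert nb.net_benefit == 0.0

    def test_treat_all_break_even_identity(self):
        # pi (1 - p_t) = (1 - pi) p_t  <=>  p_t = pi: treat-all NB = 0
        deaths = np.repeat([True, False], [25, 75])
        nb = net_benefit(np.ones(100, bool), deaths, 0.25)
        assert nb.net_benefit == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("pt", [0.0, 1.0, -0.1, 1.5])
    def test_threshold_probability_domain(self, pt):
        with pytest.raises(ValueError):
            net_benefit([True], [True], pt)


class TestConvergentValidity:
    def test_identical_and_reversed_rankings(self):
        x = np.arange(10.0)
        assert convergent_validity(x, x, n_boot=0).rho == pytest.approx(1.0)
        assert convergent_validity(x, -x, n_boot=0).rho == pytest.approx(-1.0)

    def test_hand_computed_rank_correlation(self):
        # 1 - 6*sum(d^2)/(n(n^2-1)) with d = (0,1,-1,0)
        r = convergent_validity([1, 2, 3, 4], [1, 3, 2, 4], n_boot=0)
        assert r.rho == pytest.approx(0.8)

    def test_constant_vector_reported_undefined(self):
        r = convergent_validity([1.0, 1.0, 1.0], [1, 2, 3], n_boot=0)
        assert np.isnan(r.rho)

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError):
            convergent_validity([1, 2], [1, 2])


class TestOutcomesByCategory:
    def _cohort(self, scores, died, weights=None, **extra):
        n = len(scores)
        df = pd.DataFrame({
            "score": scores,
            "died": died,
            "survey_weight": np.ones(n) if weights is None else weights,
        })
        for k, v in extra.items():
            df[k] = v
        return df

    def test_single_category_cohort_emits_empty_rows(self):
        df = self._cohort([5, 10, 20], [False, False, True])
        out = outcomes_by_category(df)
        assert list(out["category"]) == ["robust", "normal", "frail", "very_frail"]
        assert out.loc[0, "n_weighted"] == 3
        assert (out.loc[1:, "n_weighted"] == 0).all()
        assert out.loc[1:, "mortality_pct"].isna().all()

    def test_unit_weights_match_plain_proportions(self):
        scores = [5, 5, 30, 30, 40, 50]
        died = [False, True, False, True, True, True]
        out = outcomes_by_category(self._cohort(scores, died))
        robust = out[out["category"] == "robust"].iloc[0]
        assert robust["mortality_pct"] == pytest.approx(50.0)
        assert robust["pct"] == pytest.approx(100 * 2 / 6)

    def test_optional_outcome_columns_summarized(self):
        df = self._cohort([5, 5], [False, False],
                          elective=[1.0, 0.0], length_of_stay=[2.0, 4.0],
                          charges=[100.0, 300.0])
        out = outcomes_by_category(df)
        robust = out[out["category"] == "robust"].iloc[0]
        assert robust["elective_pct"] == pytest.approx(50.0)
        assert robust["mean_los"] == pytest.approx(3.0)
        assert robust["mean_charges"] == pytest.approx(200.0)


class TestScoreCalibrationWorkflow:
    def test_fit_produces_consistent_results(self):
        rng = np.random.default_rng(30)
        n = 30_000
        # right-skewed scores around 20, as the instrument produces
        scores = rng.binomial(81, 0.25, n)
        deaths = rng.random(n) < expit(-6 + 0.12 * scores)
        cal = ScoreCalibration(scores, deaths, max_score=81).fit(n_boot=20, seed=1)
        d = cal.threshold_derivation
        # generating curve: frail at 2x, very frail at 4x overall mortality
        m = cal.calibration.overall_mortality
        pm = cal.calibration.projection
        assert pm.slope == pytest.approx(0.12, abs=0.02)
        assert pm.predict(d.frail_threshold) >= 2 * m
        assert pm.predict(d.frail_threshold - 1) < 2 * m
        assert d.very_frail_threshold > d.frail_threshold
        assert "frailty threshold" in cal.summary()
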