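import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize_scalar

from markerpair import (Cohort, MarkerSpec, conditional_km, cpe, fit_cox,
                        four_model_cox, km_estimate, logrank_test,
                        null_cox_loglik, quadrant_survival_stats)
from markerpair.cohort import dichotomize
from markerpair.models import ModelFit
from markerpair.synthetic import SimConfig, simulate_cohort


class TestKaplanMeier:
    def test_all_events_product_limit_by_hand(self):
        c = km_estimate([1, 2, 3, 4, 5], [1, 1, 1, 1, 1])
        assert c.survival.tolist() == pytest.approx([0.8, 0.6, 0.4, 0.2, 0.0])
        assert c.median == 3.0

    def test_all_censored_flat_curve_undefined_median(self):
        c = km_estimate([1, 2, 3], [0, 0, 0])
        assert c.event_times.size == 0
        assert c.median is None

    def test_first_death_step(self):
        c = km_estimate([1, 4, 5, 6, 9], [1, 0, 0, 0, 0])
        assert c.survival[0] == pytest.approx(0.8)

    def test_all_event_data_equals_empirical_survival(self):
        rng = np.random.default_rng(9)
        t = rng.exponential(5, 40)
        c = km_estimate(t, np.ones(40))
        for tt, s in zip(c.event_times, c.survival):
            assert s == pytest.approx((t > tt).mean(), abs=1e-12)

    def test_curve_monotone_within_unit_interval(self):
        rng = np.random.default_rng(2)
        t = rng.exponential(5, 60)
        e = rng.binomial(1, 0.6, 60)
        c = km_estimate(t, e)
        assert (np.diff(c.survival) <= 1e-12).all()
        assert ((c.ci_low <= c.survival + 1e-12)
                & (c.survival <= c.ci_high + 1e-12)).all()

    def test_median_ci_brackets_median(self):
        rng = np.random.default_rng(14)
        t = rng.exponential(10, 120)
        c = km_estimate(t, np.ones(120))
        lo, hi = c.median_ci
        assert lo is not None and hi is not None and lo <= c.median <= hi

    def test_empty_input_errors(self):
        with pytest.raises(ValueError):
            km_estimate([], [])


class TestLogrank:
    def test_identical_groups_null(self):
        t = [1, 2, 3, 4.0] * 2
        e = [1, 1, 0, 1] * 2
        g = [0] * 4 + [1] * 4
        res = logrank_test(t, e, g)
        assert res.chi2 == pytest.approx(0.0, abs=1e-10)
        assert res.p_value == pytest.approx(1.0)

    def test_two_group_hand_oracle(self):
        t = np.array([1, 3, 5, 2, 4, 6], float)
        e = np.array([1, 1, 1, 0, 1, 1], float)
        g = np.array([0, 0, 0, 1, 1, 1])
        # observed-minus-expected tabulation over the risk sets
        O = E = V = 0.0
        for tt in sorted(set(t[e == 1])):
            at = t >= tt
            n, n1 = at.sum(), (at & (g == 0)).sum()
            d = ((t == tt) & (e == 1)).sum()
            O += ((t == tt) & (e == 1) & (g == 0)).sum()
            E += d * n1 / n
            V += d * (n1 / n) * (1 - n1 / n) * (n - d) / max(n - 1, 1)
        res = logrank_test(t, e, g)
        assert res.chi2 == pytest.approx((O - E) ** 2 / V, rel=1e-10)
        assert res.df == 1

    def test_four_groups_df_three(self, cohort300):
        lev1 = dichotomize(cohort300.data["m1"], MarkerSpec("m1")).levels
        lev2 = dichotomize(cohort300.data["m2"], MarkerSpec("m2")).levels
        g = lev1.astype(str) + "/" + lev2.astype(str)
        res = logrank_test(cohort300.data["surv_time"],
                           cohort300.data["surv_event"], g)
        assert res.df == 3

    def test_label_swap_invariance(self):
        rng = np.random.default_rng(8)
        t = rng.exponential(5, 50)
        e = rng.binomial(1, 0.7, 50)
        g = rng.binomial(1, 0.5, 50)
        assert logrank_test(t, e, g).chi2 == pytest.approx(
            logrank_test(t, e, 1 - g).chi2, rel=1e-10)

    def test_single_group_errors(self):
        with pytest.raises(ValueError):
            logrank_test([1, 2], [1, 1], [0, 0])


class TestFitCox:
    def test_zero_regressor_reduces_to_null_model(self):
        rng = np.random.default_rng(1)
        t = rng.exponential(5, 50)
        e = rng.binomial(1, 0.8, 50)
        fit = fit_cox(t, e, pd.DataFrame({"x": np.zeros(50)}))
        assert fit.coefficients["x"] == 0.0
        assert fit.loglik == pytest.approx(null_cox_loglik(t, e), abs=1e-9)

    def test_simulation_recovery_hazard_ratio_two(self):
        rng = np.random.default_rng(6)
        n = 2000
        x = rng.binomial(1, 0.5, n).astype(float)
        t = rng.exponential(1 / (0.1 * np.exp(np.log(2) * x)))
        fit = fit_cox(t, np.ones(n), pd.DataFrame({"x": x}))
        assert abs(fit.coefficients["x"] - np.log(2)) < 3 * fit.se["x"]

    def test_efron_exceeds_breslow_on_tied_data(self):
        # Breslow is known to attenuate toward zero under heavy ties;
        # the Breslow partial likelihood here is an independent oracle.
        rng = np.random.default_rng(5)
        n = 120
        x = rng.binomial(1, 0.5, n).astype(float)
        t = np.ceil(rng.exponential(1 / (0.2 * np.exp(0.8 * x))))
        e = np.ones(n)
        efron = fit_cox(t, e, pd.DataFrame({"x": x})).coefficients["x"]

        def breslow_negll(b):
            ll = 0.0
            for tt in np.unique(t):
                tied = t == tt
                ll += b * x[tied].sum() - tied.sum() * np.log(
                    np.exp(b * x[t >= tt]).sum())
            return -ll

        breslow = minimize_scalar(breslow_negll, bounds=(-5, 5),
                                  method="bounded").x
        assert efron > breslow > 0

    def test_monotone_likelihood_flagged(self):
        t = np.arange(1.0, 31.0)
        x = -t  # perfectly orders the events
        fit = fit_cox(t, np.ones(30), pd.DataFrame({"x": x}))
        assert fit.flagged

    def test_no_events_errors(self):
        with pytest.raises(ValueError):
            fit_cox([1, 2], [0, 0], pd.DataFrame({"x": [0.0, 1.0]}))


class TestCPE:
    def test_constant_linear_predictor_is_half(self):
        fit = ModelFit("cox", "M1", {"x": 0.0}, {"x": 1.0}, -1.0, 4, True)
        res = cpe(fit, pd.DataFrame({"x": [1.0, 2.0, 3.0, 4.0]}))
        assert res.cpe == pytest.approx(0.5)

    def test_single_pair_closed_form(self):
        fit = ModelFit("cox", "M1", {"x": np.log(3)}, {"x": 1.0}, -1.0, 2, True)
        res = cpe(fit, pd.DataFrame({"x": [0.0, 1.0]}))
        assert res.cpe == pytest.approx(0.75)
        assert res.n_pairs == 1

    def test_three_point_average(self):
        fit = ModelFit("cox", "M1", {"x": np.log(3)}, {"x": 1.0}, -1.0, 3, True)
        res = cpe(fit, pd.DataFrame({"x": [0.0, 0.0, 1.0]}))
        assert res.cpe == pytest.approx((0.5 + 0.75 + 0.75) / 3)

    def test_matches_brute_force_pairwise(self):
        rng = np.random.default_rng(17)
        n = 200
        design = pd.DataFrame({"a": rng.normal(size=n), "b": rng.normal(size=n)})
        fit = ModelFit("cox", "M1+M2", {"a": 0.7, "b": -0.3},
                       {"a": 1.0, "b": 1.0}, -1.0, n, True)
        eta = design.to_numpy() @ np.array([0.7, -0.3])
        brute = np.mean([1 / (1 + np.exp(-abs(eta[i] - eta[j])))
                         for i in range(n) for j in range(i + 1, n)])
        assert cpe(fit, design).cpe == pytest.approx(brute, abs=1e-12)

    def test_too_few_samples(self):
        fit = ModelFit("cox", "M1", {"x": 1.0}, {"x": 1.0}, -1.0, 1, True)
        with pytest.raises(ValueError):
            cpe(fit, pd.DataFrame({"x": [1.0]}))


class TestFourModelCox:
    def test_contract(self, cohort300):
        fm = four_model_cox(cohort300, "m1", "m2")
        assert fm.status == "evaluated"
        assert fm.comparison("M1*M2", "M1+M2").df == 1
        assert len({f.n_used for f in fm.fits.values()}) == 1
        for comp in fm.comparisons.values():
            assert comp.stat >= 0.0
        for perf in fm.performance.values():
            assert 0.5 <= perf.cpe <= 1.0

    def test_min_events_guard(self):
        co = simulate_cohort(SimConfig(n=60, seed=3, lambda0=0.001,
                                       censor_rate=0.2, admin_tau=5.0))
        fm = four_model_cox(co, "m1", "m2")
        assert fm.status == "skipped" and "events" in fm.skip_reason


class TestConditionalKM:
    def test_consistency_with_manual_subsets(self, cohort300):
        m1, m2 = MarkerSpec("m1"), MarkerSpec("m2")
        rep = conditional_km(cohort300, m1, m2)
        lev1 = dichotomize(cohort300.data["m1"], m1).levels
        lev2 = dichotomize(cohort300.data["m2"], m2).levels
        sub = cohort300.data[lev1 == "high"]
        oracle = logrank_test(sub["surv_time"], sub["surv_event"],
                              lev2[lev1 == "high"])
        entry = rep.entries["m2_within_m1_high"]
        assert entry["p_value"] == pytest.approx(oracle.p_value, rel=1e-10)
        assert entry["p_adjusted"] == pytest.approx(
            min(1.0, 4 * oracle.p_value))

    def test_family_of_four(self, cohort300):
        rep = conditional_km(cohort300, MarkerSpec("m1"), MarkerSpec("m2"))
        assert set(rep.entries) == {"m2_within_m1_high", "m2_within_m1_low",
                                    "m1_within_m2_high", "m1_within_m2_low"}

    def test_identical_survival_within_stratum_p_near_one(self):
        # M2 independent of survival: within-stratum comparisons ~ null
        t = np.tile([1, 2, 3, 4, 5, 6, 7, 8.0], 4)
        df = pd.DataFrame({
            "response": np.tile([0.0, 1.0], 16),
            "surv_time": t, "surv_event": np.ones(32),
            "m1": np.repeat([0.0, 1.0], 16),
            "m2": np.tile(np.repeat([0.0, 1.0], 8), 2),
        }, index=[f"s{i}" for i in range(32)])
        co = Cohort(df, ["m1", "m2"], [], has_response=True, has_survival=True)
        rep = conditional_km(co, MarkerSpec("m1", kind="binary"),
                             MarkerSpec("m2", kind="binary"))
        assert rep.entries["m2_within_m1_high"]["p_value"] == pytest.approx(1.0)


class TestQuadrantSurvival:
    def test_medians_and_fisher_match_component_calls(self, cohort300):
        from markerpair import fisher_exact_2x2
        m1, m2 = MarkerSpec("m1"), MarkerSpec("m2")
        qs = quadrant_survival_stats(cohort300, m1, m2)
        lev1 = dichotomize(cohort300.data["m1"], m1).levels
        lev2 = dichotomize(cohort300.data["m2"], m2).levels
        mask = (lev1 == "high") & (lev2 == "high")
        sub = cohort300.data[mask]
        oracle = km_estimate(sub["surv_time"], sub["surv_event"])
        assert qs.medians["R1"] == oracle.median
        table = [[qs.counts["R1"], qs.counts["R4"]],
                 [qs.counts["R2"], qs.counts["R3"]]]
        assert qs.fisher.p_value == pytest.approx(
            fisher_exact_2x2(table).p_value)

    def test_identical_groups_equal_medians(self):
        base = pd.DataFrame({
            "surv_time": np.tile([1, 2, 3, 4, 5.0], 4),
            "surv_event": np.ones(20),
            "m1": np.repeat([0.0, 1.0], 10),
            "m2": np.tile(np.repeat([0.0, 1.0], 5), 2),
        }, index=[f"s{i}" for i in range(20)])
        co = Cohort(base, ["m1", "m2"], [], has_response=False,
                    has_survival=True)
        qs = quadrant_survival_stats(co, MarkerSpec("m1", kind="binary"),
                                     MarkerSpec("m2", kind="binary"))
        assert len(set(qs.medians.values())) == 1
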