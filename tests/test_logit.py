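import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps
from sklearn.base import clone

from markerpair import (DualMarkerLogit, LRTResult, ModelFit, fit_logistic,
                        four_model_logit, lrt, roc_auc_delong)
from markerpair.synthetic import SimConfig, simulate_cohort


def _stub(loglik, params, kind="logit", n=100):
    coefs = {p: 0.0 for p in params}
    return ModelFit(kind, "custom", coefs, dict(coefs), loglik, n, True)


class TestFitLogistic:
    def test_intercept_only_closed_form_log_odds(self):
        y = np.array([1] * 6 + [0] * 4)
        fit = fit_logistic(y, pd.DataFrame(index=range(10)))
        assert fit.coefficients["Intercept"] == pytest.approx(np.log(6 / 4), abs=1e-6)

    def test_grouped_2x2_coefficient_is_log_odds_ratio(self):
        # responders x marker counts [[30,10],[10,30]] -> sample OR = 9
        x = np.repeat([1.0, 1.0, 0.0, 0.0], [30, 10, 10, 30])
        y = np.repeat([1.0, 0.0, 1.0, 0.0], [30, 10, 10, 30])
        fit = fit_logistic(y, pd.DataFrame({"x": x}))
        assert fit.coefficients["x"] == pytest.approx(np.log(9), abs=1e-6)
        assert fit.converged and not fit.flagged

    def test_perfect_separation_flagged(self):
        y = np.array([0] * 10 + [1] * 10, float)
        x = np.arange(20, dtype=float)
        fit = fit_logistic(y, pd.DataFrame({"x": x}))
        assert fit.flagged

    def test_constant_response_errors(self):
        with pytest.raises(ValueError):
            fit_logistic(np.ones(10), pd.DataFrame({"x": np.arange(10.0)}))


class TestLRT:
    def test_chi_square_df1_oracle(self):
        res = lrt(_stub(-50.0, ["a", "b"]), _stub(-52.0, ["a"]))
        assert res.stat == pytest.approx(4.0)
        assert res.df == 1
        assert res.p_value == pytest.approx(sps.chi2.sf(4.0, 1), rel=1e-12)

    def test_equal_loglik_p_one(self):
        res = lrt(_stub(-50.0, ["a", "b"]), _stub(-50.0, ["a"]))
        assert res.stat == 0.0 and res.p_value == 1.0

    def test_df2_uses_chi2_two(self):
        res = lrt(_stub(-48.0, ["a", "b", "c"]), _stub(-51.0, ["a"]))
        assert res.df == 2
        assert res.p_value == pytest.approx(sps.chi2.sf(6.0, 2), rel=1e-12)

    def test_n_used_mismatch_is_hard_error(self):
        with pytest.raises(ValueError, match="n_used"):
            lrt(_stub(-50.0, ["a", "b"], n=100), _stub(-52.0, ["a"], n=99))

    def test_non_nested_rejected(self):
        with pytest.raises(ValueError, match="nested"):
            lrt(_stub(-50.0, ["a", "b"]), _stub(-52.0, ["c"]))


class TestDeLongAUC:
    def test_perfect_separation(self):
        res = roc_auc_delong([1, 2, 3, 4], [0, 0, 1, 1])
        assert res.auc == 1.0 and res.ci_high == 1.0

    def test_interleaved(self):
        assert roc_auc_delong([1, 2, 3, 4], [0, 1, 0, 1]).auc == pytest.approx(0.75)

    def test_all_tied_scores(self):
        assert roc_auc_delong([2, 2, 2, 2], [0, 1, 0, 1]).auc == pytest.approx(0.5)

    def test_one_class_errors(self):
        with pytest.raises(ValueError):
            roc_auc_delong([1, 2], [1, 1])

    def test_auc_equals_brute_force_pair_count(self):
        rng = np.random.default_rng(21)
        for _ in range(20):
            n = rng.integers(6, 50)
            scores = np.round(rng.normal(size=n), 1)  # induce ties
            labels = rng.binomial(1, 0.4, n)
            if labels.sum() in (0, n):
                continue
            pos = scores[labels == 1]
            neg = scores[labels == 0]
            wins = sum((p > q) + 0.5 * (p == q) for p in pos for q in neg)
            brute = wins / (len(pos) * len(neg))
            assert roc_auc_delong(scores, labels).auc == pytest.approx(brute, abs=1e-12)

    def test_ci_brackets_auc(self):
        rng = np.random.default_rng(4)
        scores = rng.normal(size=80)
        labels = rng.binomial(1, 0.5, 80)
        res = roc_auc_delong(scores, labels)
        assert res.ci_low <= res.auc <= res.ci_high


class TestFourModelLogit:
    def test_all_fits_share_complete_case_set(self, cohort300):
        fm = four_model_logit(cohort300, "m1", "m2")
        assert fm.status == "evaluated"
        assert len({f.n_used for f in fm.fits.values()}) == 1
        assert fm.comparison("M1*M2", "M1").df == 2
        assert fm.comparison("M1+M2", "M1").df == 1

    def test_identical_model_compared_to_itself_is_null(self, cohort300):
        fm = four_model_logit(cohort300, "m1", "m2")
        full = fm.fits["M1+M2"]
        # same fit with one extra (zero-information) parameter name
        padded = ModelFit(full.kind, full.formula_tag,
                          {**full.coefficients, "pad": 0.0},
                          {**full.se, "pad": 1.0}, full.loglik, full.n_used,
                          True)
        res = lrt(padded, full)
        assert res.stat == 0.0 and res.p_value == 1.0

    def test_collinear_copy_skipped(self, cohort300):
        co = cohort300
        df = co.data.copy()
        df["m1_copy"] = df["m1"]
        from markerpair import Cohort
        co2 = Cohort(df, co.markers + ["m1_copy"], co.covariates,
                     has_response=True, has_survival=True)
        fm = four_model_logit(co2, "m1", "m1_copy")
        assert fm.status == "skipped" and "collinear" in fm.skip_reason

    def test_lrt_invariant_to_affine_rescaling(self, cohort300):
        co = cohort300
        df = co.data.copy()
        df["m2_scaled"] = 1000.0 * df["m2"] + 5.0
        from markerpair import Cohort
        co2 = Cohort(df, co.markers + ["m2_scaled"], co.covariates,
                     has_response=True, has_survival=True)
        p0 = four_model_logit(co, "m1", "m2").comparison("M1+M2", "M1").p_value
        p1 = four_model_logit(co2, "m1", "m2_scaled").comparison("M1+M2", "M1").p_value
        assert p1 == pytest.approx(p0, rel=1e-6)

    def test_interaction_model_auc_dominates_single(self):
        for seed in (1, 2, 3):
            co = simulate_cohort(SimConfig(n=250, seed=seed, b12=0.3))
            fm = four_model_logit(co, "m1", "m2")
            assert (fm.performance["M1*M2"].auc
                    >= fm.performance["M1"].auc - 1e-9)

    def test_below_min_n_skipped(self):
        co = simulate_cohort(SimConfig(n=15, seed=0))
        fm = four_model_logit(co, "m1", "m2")
        assert fm.status == "skipped" and "min_n" in fm.skip_reason

    def test_sklearn_estimator_contract(self, cohort300):
        est = DualMarkerLogit("m1", "m2", min_n=25)
        assert est.get_params()["min_n"] == 25
        est2 = clone(est).set_params(min_n=30)
        assert est2.min_n == 30
        est.fit(cohort300)
        assert est.result_.status == "evaluated"
        probs = est.predict_proba(cohort300)
        assert ((probs >= 0) & (probs <= 1)).all()
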