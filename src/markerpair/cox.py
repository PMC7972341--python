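"""Survival side: Kaplan-Meier estimation, log-rank tests, Cox proportional
hazards with Efron tie handling, the four-model Cox family, the Gonen-Heller
concordance probability estimate (CPE), conditional KM comparisons and
quadrant survival summaries.

The CPE is model-based: it is computed from the fitted linear predictors
only, never from the observed event ordering, as

    K = (2 / n(n-1)) * sum_{i<j} 1 / (1 + exp(-|eta_i - eta_j|))

which equals the concordance probability of a proportional-hazards model at
the fitted coefficients and is exactly 0.5 when all linear predictors tie.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from scipy import stats as sps
from scipy.spatial.distance import pdist
from sklearn.base import BaseEstimator

from .cohort import (Cohort, CohortError, MarkerSpec, QUADRANTS,
                     assign_quadrants, dichotomize)
from .models import (COMPARISONS, FourModelFit, ModelFit, build_pair_design,
                     lrt)
from .stats import TestResult, bonferroni_adjust, fisher_exact_2x2

__all__ = ["KMCurve", "LogrankResult", "CPEResult", "ConditionalKMReport",
           "km_estimate", "logrank_test", "fit_cox", "cpe",
           "DualMarkerCox", "four_model_cox", "conditional_km",
           "quadrant_survival_stats", "null_cox_loglik"]


@dataclass
class KMCurve:
    event_times: np.ndarray      # sorted distinct times with >= 1 event
    n_at_risk: np.ndarray
    n_events: np.ndarray
    survival: np.ndarray         # product-limit S(t) at the event times
    se: np.ndarray               # Greenwood standard errors of S(t)
    ci_low: np.ndarray           # pointwise CI on the log-survival scale
    ci_high: np.ndarray
    median: float | None
    median_ci: tuple             # (low, high), either side possibly None
    n: int = 0
    n_observed_events: int = 0

    def to_frame(self) -> pd.DataFrame:
        """Tidy long table of the curve."""
        return pd.DataFrame({
            "time": self.event_times, "n_at_risk": self.n_at_risk,
            "n_events": self.n_events, "survival": self.survival,
            "se": self.se, "ci_low": self.ci_low, "ci_high": self.ci_high,
        })


@dataclass
class LogrankResult:
    chi2: float
    df: int
    p_value: float

    def to_dict(self) -> dict:
        return {"chi2": float(self.chi2), "df": int(self.df),
                "p_value": float(self.p_value)}


@dataclass
class CPEResult:
    cpe: float
    n_pairs: int

    def to_dict(self) -> dict:
        return {"cpe": float(self.cpe), "n_pairs": int(self.n_pairs)}


def _cross_time(times: np.ndarray, curve: np.ndarray) -> float | None:
    """Smallest time at which a (non-increasing) curve drops to <= 0.5."""
    below = np.nonzero(curve <= 0.5)[0]
    return float(times[below[0]]) if below.size else None


def km_estimate(times, events, level: float = 0.95) -> KMCurve:
    """Product-limit survival estimate with Greenwood variance.

    Pointwise confidence bands are built on the log-survival scale,
    ``S * exp(+- z * sqrt(var(log S)))`` with ``var(log S)`` the Greenwood
    sum, clipped to [0, 1].  The median is the smallest time with S <= 0.5;
    its CI intersects the confidence bands with 0.5 (a side that never
    crosses is reported as None).
    """
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=float)
    if t.size == 0:
        raise ValueError("km_estimate: empty input")
    if (t < 0).any():
        raise ValueError("km_estimate: negative times")
    kmf = KaplanMeierFitter().fit(t, e)
    tab = kmf.event_table
    tab = tab[tab["observed"] > 0]
    et = tab.index.to_numpy(dtype=float)
    d = tab["observed"].to_numpy(dtype=float)
    n = tab["at_risk"].to_numpy(dtype=float)
    surv = np.cumprod(1.0 - d / n)
    with np.errstate(divide="ignore", invalid="ignore"):
        gw = np.cumsum(np.where(n > d, d / (n * (n - d)), np.inf))
        se = surv * np.sqrt(gw)
        z = sps.norm.ppf(0.5 + level / 2)
        lo = surv * np.exp(-z * np.sqrt(gw))
        hi = surv * np.exp(z * np.sqrt(gw))
    zero = surv <= 0
    se[zero], lo[zero], hi[zero] = 0.0, 0.0, 0.0
    lo, hi = np.clip(lo, 0, 1), np.clip(hi, 0, 1)
    median = _cross_time(et, surv)
    median_ci = (_cross_time(et, lo), _cross_time(et, hi))
    return KMCurve(et, n, d, surv, se, lo, hi, median, median_ci,
                   n=int(t.size), n_observed_events=int(e.sum()))


def logrank_test(times, events, groups) -> LogrankResult:
    """k-group log-rank chi-square (hypergeometric variance), df = k - 1."""
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=float)
    g = np.asarray(groups)
    labels = pd.unique(g)
    if labels.size < 2:
        raise ValueError("logrank_test: need at least 2 non-empty groups")
    if e.sum() < 1:
        raise ValueError("logrank_test: need at least one event")
    res = multivariate_logrank_test(t, g, e)
    return LogrankResult(float(res.test_statistic), int(labels.size - 1),
                         float(res.p_value))


def null_cox_loglik(times, events) -> float:
    """Cox partial log-likelihood at beta = 0 (Efron = Breslow at the null)."""
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=float)
    ll = 0.0
    for tt in np.unique(t[e == 1]):
        n_risk = int((t >= tt).sum())
        dj = int(((t == tt) & (e == 1)).sum())
        ll -= sum(np.log(n_risk - l) for l in range(dj))
    return float(ll)


def fit_cox(times, events, design, *, tag: str = "custom",
            separation_threshold: float = 15.0) -> ModelFit:
    """Cox proportional-hazards fit via partial-likelihood maximization with
    the Efron correction for tied event times.

    Zero-variance regressors are held at coefficient 0 (they carry no
    information); monotone partial likelihood (a regressor perfectly
    ordering the events) is detected from non-convergence or a diverging
    coefficient and flagged for the caller to skip.
    """
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=float)
    if e.sum() < 1:
        raise ValueError("fit_cox: no events")
    design = pd.DataFrame(design)
    names = list(design.columns)
    active = [c for c in names if design[c].nunique() > 1]
    dropped = [c for c in names if c not in active]
    coefs = {c: 0.0 for c in names}
    ses = {c: np.nan for c in names}
    flagged, reason, converged = False, None, True
    if active:
        df = design[active].copy()
        df["__time"], df["__event"] = t, e
        try:
            with warnings.catch_warnings(record=True) as caught:
                warnings.simplefilter("always")
                cph = CoxPHFitter()
                cph.fit(df, duration_col="__time", event_col="__event")
            msgs = " ".join(str(w.message).lower() for w in caught)
            if "convergence" in msgs or "separation" in msgs or "monotone" in msgs:
                flagged, reason = True, "possible monotone likelihood / separation"
            for c in active:
                coefs[c] = float(cph.params_[c])
                ses[c] = float(cph.standard_errors_[c])
            ll = float(cph.log_likelihood_)
        except Exception as exc:
            flagged, reason, converged = True, f"fit failed: {exc}", False
            for c in active:
                coefs[c] = np.nan
            ll = np.nan
    else:
        ll = null_cox_loglik(t, e)
    if not flagged and active:
        if max(abs(coefs[c]) for c in active) > separation_threshold:
            flagged = True
            reason = "diverging coefficient (monotone likelihood)"
    eta = design.to_numpy(dtype=float) @ np.array(
        [coefs[c] if np.isfinite(coefs[c]) else 0.0 for c in names])
    return ModelFit("cox", tag, coefs, ses, ll, int(t.size), converged,
                    flagged=flagged, flag_reason=reason,
                    covariate_names=names, linear_predictor=eta)


def cpe(fit: ModelFit, design) -> CPEResult:
    """Gonen-Heller concordance probability estimate from linear predictors.

    Mean over all unordered sample pairs of ``1 / (1 + exp(-|eta_i - eta_j|))``.
    """
    design = pd.DataFrame(design)
    if len(design) < 2:
        raise ValueError("cpe: need at least 2 samples")
    beta = np.array([fit.coefficients[c] for c in design.columns])
    eta = design.to_numpy(dtype=float) @ beta
    d = pdist(eta.reshape(-1, 1), metric="cityblock")   # |eta_i - eta_j|
    vals = 1.0 / (1.0 + np.exp(-d))
    return CPEResult(float(vals.mean()), int(d.size))


class DualMarkerCox(BaseEstimator):
    """Four-model Cox evaluation of one biomarker pair.

    Same contract as :class:`markerpair.logit.DualMarkerLogit` but on the
    survival outcome: Efron-tie Cox fits, LRTs on partial log-likelihoods,
    the interaction Wald test, and a Gonen-Heller CPE per model.

    ``min_events`` (default 10) guards against meaningless likelihood-ratio
    comparisons in strata with almost no events.
    """

    def __init__(self, m1, m2, covariates=None, min_n: int = 20,
                 min_events: int = 10, collinearity_r: float = 0.999,
                 separation_threshold: float = 15.0):
        self.m1 = m1
        self.m2 = m2
        self.covariates = covariates
        self.min_n = min_n
        self.min_events = min_events
        self.collinearity_r = collinearity_r
        self.separation_threshold = separation_threshold

    def fit(self, cohort: Cohort, y=None):
        m1 = self.m1 if isinstance(self.m1, MarkerSpec) else MarkerSpec(str(self.m1))
        m2 = self.m2 if isinstance(self.m2, MarkerSpec) else MarkerSpec(str(self.m2))
        covs = list(self.covariates or [])
        out = FourModelFit("cox", m1.name, m2.name)

        def skipped(reason):
            out.status, out.skip_reason = "skipped", reason
            self.result_ = out
            return self

        df = build_pair_design(cohort, m1, m2, covs, outcome="survival")
        out.n_used = len(df)
        if len(df) < self.min_n:
            return skipped(f"complete cases {len(df)} < min_n {self.min_n}")
        n_events = int(df["surv_event"].sum())
        if n_events < self.min_events:
            return skipped(f"events {n_events} < min_events {self.min_events}")
        x1 = df[m1.name].to_numpy()
        x2 = df[m2.name].to_numpy()
        if np.std(x1) == 0 or np.std(x2) == 0:
            return skipped("constant marker on the complete-case set")
        r = np.corrcoef(x1, x2)[0, 1]
        if abs(r) > self.collinearity_r:
            return skipped(f"markers collinear (|r|={abs(r):.4f})")

        inter = df.attrs["interaction"]
        t = df["surv_time"].to_numpy()
        e = df["surv_event"].to_numpy()
        columns = {"M1": [m1.name], "M2": [m2.name],
                   "M1+M2": [m1.name, m2.name],
                   "M1*M2": [m1.name, m2.name, inter]}
        for tag, cols in columns.items():
            out.fits[tag] = fit_cox(t, e, df[cols + covs], tag=tag,
                                    separation_threshold=self.separation_threshold)
        bad = [tg for tg, f in out.fits.items() if f.flagged]
        if bad:
            return skipped("flagged fit in " + ", ".join(
                f"{tg} ({out.fits[tg].flag_reason})" for tg in bad))

        for full_tag, red_tag in COMPARISONS:
            out.comparisons[f"{full_tag}_vs_{red_tag}"] = lrt(
                out.fits[full_tag], out.fits[red_tag])
        out.interaction_wald_p = out.fits["M1*M2"].wald_p(inter)
        for tag, cols in columns.items():
            out.performance[tag] = cpe(out.fits[tag], df[cols + covs])
        self.result_ = out
        self.fits_ = out.fits
        self.comparisons_ = out.comparisons
        self.cpe_ = out.performance
        self.interaction_wald_p_ = out.interaction_wald_p
        self.n_used_ = out.n_used
        return self


def four_model_cox(cohort: Cohort, m1, m2, covariates=None,
                   **kwargs) -> FourModelFit:
    """Functional wrapper around :class:`DualMarkerCox`."""
    return DualMarkerCox(m1, m2, covariates, **kwargs).fit(cohort).result_


@dataclass
class ConditionalKMReport:
    """Four stratified 2-group log-rank comparisons with Bonferroni (m=4).

    Keys: ``m2_within_m1_high``, ``m2_within_m1_low``,
    ``m1_within_m2_high``, ``m1_within_m2_low``.  Each entry holds the raw
    and adjusted p, the stratum size, and per-level KM curves for plotting;
    non-evaluable strata keep the family size at 4.
    """
    entries: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        out = {}
        for k, v in self.entries.items():
            out[k] = {"evaluable": v["evaluable"], "n": v["n"],
                      "p_value": v.get("p_value"), "p_adjusted": v.get("p_adjusted"),
                      "reason": v.get("reason")}
        return out


def _surv_frame(cohort: Cohort, m1: MarkerSpec, m2: MarkerSpec) -> pd.DataFrame:
    if not cohort.has_survival:
        raise CohortError("cohort has no survival outcome")
    lev1 = dichotomize(cohort.data[m1.name], m1).levels
    lev2 = dichotomize(cohort.data[m2.name], m2).levels
    df = pd.DataFrame({"time": cohort.data["surv_time"],
                       "event": cohort.data["surv_event"],
                       "lev1": lev1, "lev2": lev2})
    return df.dropna()


def conditional_km(cohort: Cohort, m1: MarkerSpec, m2: MarkerSpec) -> ConditionalKMReport:
    """Survival of one marker within each level of the other.

    Four log-rank tests — M2 high-vs-low within M1-high and within M1-low,
    and M1 high-vs-low within M2-high and within M2-low — Bonferroni
    adjusted as one family of 4.
    """
    df = _surv_frame(cohort, m1, m2)
    plan = {
        "m2_within_m1_high": ("lev1", m1.label_high, "lev2"),
        "m2_within_m1_low": ("lev1", m1.label_low, "lev2"),
        "m1_within_m2_high": ("lev2", m2.label_high, "lev1"),
        "m1_within_m2_low": ("lev2", m2.label_low, "lev1"),
    }
    rep = ConditionalKMReport()
    for key, (strat_col, strat_level, comp_col) in plan.items():
        sub = df[df[strat_col] == strat_level]
        entry = {"n": int(len(sub)), "evaluable": False}
        levels = sub[comp_col].unique()
        if len(sub) == 0 or len(levels) < 2 or sub["event"].sum() < 1:
            entry["reason"] = "empty stratum or single level or no events"
        else:
            res = logrank_test(sub["time"], sub["event"], sub[comp_col])
            entry.update(evaluable=True, p_value=res.p_value,
                         p_adjusted=bonferroni_adjust(res.p_value, 4),
                         logrank=res,
                         curves={str(l): km_estimate(sub.loc[sub[comp_col] == l, "time"],
                                                     sub.loc[sub[comp_col] == l, "event"])
                                 for l in sorted(map(str, levels))})
        rep.entries[key] = entry
    return rep


@dataclass
class QuadrantSurvivalStats:
    counts: dict
    medians: dict                 # quadrant -> median or None
    median_cis: dict              # quadrant -> (low, high)
    curves: dict                  # quadrant -> KMCurve (missing if empty)
    fisher: TestResult
    logrank: LogrankResult | None


def quadrant_survival_stats(cohort: Cohort, m1: MarkerSpec,
                            m2: MarkerSpec) -> QuadrantSurvivalStats:
    """Per-quadrant KM medians with CIs, the 4-group log-rank test, and the
    Fisher exact independence test on the 2x2 high/low marker table."""
    df = _surv_frame(cohort, m1, m2)
    qa = assign_quadrants(df["lev1"], df["lev2"],
                          high=m1.label_high, low=m1.label_low)
    df = df.assign(quadrant=qa.quadrant)
    table = [[qa.counts["R1"], qa.counts["R4"]],   # M1 high: M2 high / low
             [qa.counts["R2"], qa.counts["R3"]]]   # M1 low
    fisher = fisher_exact_2x2(table)
    medians, cis, curves = {}, {}, {}
    for q in QUADRANTS:
        sub = df[df["quadrant"] == q]
        if len(sub) == 0:
            medians[q], cis[q] = None, (None, None)
            continue
        curve = km_estimate(sub["time"], sub["event"])
        curves[q] = curve
        medians[q], cis[q] = curve.median, curve.median_ci
    present = df["quadrant"].dropna()
    lr = None
    if present.nunique() >= 2 and df.loc[present.index, "event"].sum() >= 1:
        sub = df[df["quadrant"].notna()]
        lr = logrank_test(sub["time"], sub["event"], sub["quadrant"])
    return QuadrantSurvivalStats(qa.counts, medians, cis, curves, fisher, lr)
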