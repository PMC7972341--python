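"""Binary-response side: logistic fits, the four-model family, nested
likelihood-ratio comparisons, and ROC/AUC with DeLong confidence intervals.

ROC curves (single- and dual-marker alike) are computed on the fitted
response probabilities of the corresponding logistic model, so a marker that
is *negatively* associated with response still yields AUC >= 0.5 and all four
curves are directly comparable on one plot.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps
from sklearn.base import BaseEstimator

from .cohort import Cohort, CohortError, MarkerSpec
from .models import (COMPARISONS, FourModelFit, LRTResult, ModelFit,
                     build_pair_design, lrt)

__all__ = ["AUCResult", "fit_logistic", "roc_auc_delong",
           "DualMarkerLogit", "four_model_logit"]


@dataclass
class AUCResult:
    auc: float
    ci_low: float
    ci_high: float
    n_pos: int
    n_neg: int

    def to_dict(self) -> dict:
        return {"auc": float(self.auc), "ci_low": float(self.ci_low),
                "ci_high": float(self.ci_high),
                "n_pos": int(self.n_pos), "n_neg": int(self.n_neg)}


def roc_auc_delong(scores, labels, level: float = 0.95) -> AUCResult:
    """AUC (Mann-Whitney with ties counting 0.5) and a DeLong CI.

    The variance comes from DeLong's structural components: the empirical
    placement values of each positive among the negatives and vice versa.
    The normal-theory interval is truncated to [0, 1].
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=float)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    m, n = pos.size, neg.size
    if m == 0 or n == 0:
        raise ValueError("roc_auc_delong: both classes must be present")
    tz = sps.rankdata(np.concatenate([pos, neg]))
    tx = sps.rankdata(pos)
    ty = sps.rankdata(neg)
    v10 = (tz[:m] - tx) / n           # placement of each positive
    v01 = 1.0 - (tz[m:] - ty) / m     # placement of each negative
    auc = float(v10.mean())
    s10 = v10.var(ddof=1) if m > 1 else 0.0
    s01 = v01.var(ddof=1) if n > 1 else 0.0
    se = np.sqrt(s10 / m + s01 / n)
    z = sps.norm.ppf(0.5 + level / 2)
    return AUCResult(auc, float(max(0.0, auc - z * se)),
                     float(min(1.0, auc + z * se)), m, n)


def fit_logistic(response, design, *, tag: str = "custom",
                 separation_threshold: float = 15.0,
                 maxiter: int = 25) -> ModelFit:
    """Maximum-likelihood logistic fit with intercept.

    Quasi-separation is detected from non-convergence or any coefficient
    beyond ``separation_threshold`` in absolute value; such fits are flagged
    (and downstream excluded from LRT comparisons with a recorded reason)
    rather than silently reported.
    """
    y = np.asarray(response, dtype=float)
    if np.unique(y[~np.isnan(y)]).size < 2:
        raise ValueError("fit_logistic: response is constant")
    design = pd.DataFrame(design)
    X = sm.add_constant(design, has_constant="add")
    names = ["Intercept"] + list(design.columns)
    flagged, reason, converged = False, None, False
    try:
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            res = sm.Logit(y, X).fit(disp=0, maxiter=maxiter,
                                     method="newton", tol=1e-9)
        converged = bool(res.mle_retvals.get("converged", False))
        if any("separation" in str(w.message).lower() for w in caught):
            flagged, reason = True, "perfect separation"
        coefs = dict(zip(names, np.asarray(res.params, dtype=float)))
        ses = dict(zip(names, np.asarray(res.bse, dtype=float)))
        ll = float(res.llf)
        eta = np.asarray(res.fittedvalues, dtype=float)
        prob = 1.0 / (1.0 + np.exp(-eta))
    except Exception as exc:  # singular / separation errors from the optimizer
        flagged, reason = True, f"fit failed: {exc}"
        coefs = {k: np.nan for k in names}
        ses = dict(coefs)
        ll, eta, prob = np.nan, None, None
    if not flagged and (not converged
                        or max(abs(v) for v in coefs.values()) > separation_threshold):
        flagged = True
        reason = "non-convergence or quasi-separation (diverging coefficient)"
    return ModelFit("logit", tag, coefs, ses, ll, int(y.size), converged,
                    flagged=flagged, flag_reason=reason,
                    covariate_names=list(design.columns),
                    linear_predictor=eta, fitted_prob=prob)


def _as_spec(marker) -> MarkerSpec:
    return marker if isinstance(marker, MarkerSpec) else MarkerSpec(str(marker))


class DualMarkerLogit(BaseEstimator):
    """Four-model logistic evaluation of one biomarker pair.

    Fits ``response ~ M1``, ``~ M2``, ``~ M1 + M2`` and ``~ M1 + M2 + M1:M2``
    (each plus any covariates, additively) on the identical complete-case
    set, and exposes the five nested LRT comparisons, the interaction Wald
    test and per-model AUC with DeLong intervals.

    Parameters
    ----------
    m1, m2 : marker name or :class:`MarkerSpec`.
    covariates : covariate column names appended to every model.
    min_n : minimum complete cases (default 20).
    min_per_class : minimum responders and non-responders (default 5).
    collinearity_r : |Pearson r| between the marker regressors above which
        the pair is skipped as collinear.

    Attributes (after ``fit``)
    --------------------------
    result_ : :class:`FourModelFit`
    fits_, comparisons_, auc_, interaction_wald_p_, n_used_ : shortcuts into
        ``result_`` when the pair was evaluated.
    """

    def __init__(self, m1, m2, covariates=None, min_n: int = 20,
                 min_per_class: int = 5, collinearity_r: float = 0.999,
                 separation_threshold: float = 15.0):
        self.m1 = m1
        self.m2 = m2
        self.covariates = covariates
        self.min_n = min_n
        self.min_per_class = min_per_class
        self.collinearity_r = collinearity_r
        self.separation_threshold = separation_threshold

    def fit(self, cohort: Cohort, y=None):
        m1, m2 = _as_spec(self.m1), _as_spec(self.m2)
        covs = list(self.covariates or [])
        out = FourModelFit("logit", m1.name, m2.name)

        def skipped(reason):
            out.status, out.skip_reason = "skipped", reason
            self.result_ = out
            return self

        try:
            df = build_pair_design(cohort, m1, m2, covs, outcome="response")
        except CohortError as exc:
            raise
        out.n_used = len(df)
        y01 = df["response"].to_numpy()
        if len(df) < self.min_n:
            return skipped(f"complete cases {len(df)} < min_n {self.min_n}")
        n_pos = int(y01.sum())
        if min(n_pos, len(df) - n_pos) < self.min_per_class:
            return skipped(f"a response class has < {self.min_per_class} samples")
        x1 = df[m1.name].to_numpy()
        x2 = df[m2.name].to_numpy()
        if np.std(x1) == 0 or np.std(x2) == 0:
            return skipped("constant marker on the complete-case set")
        r = np.corrcoef(x1, x2)[0, 1]
        if abs(r) > self.collinearity_r:
            return skipped(f"markers collinear (|r|={abs(r):.4f})")

        inter = df.attrs["interaction"]
        columns = {"M1": [m1.name], "M2": [m2.name],
                   "M1+M2": [m1.name, m2.name],
                   "M1*M2": [m1.name, m2.name, inter]}
        for tag, cols in columns.items():
            out.fits[tag] = fit_logistic(
                y01, df[cols + covs], tag=tag,
                separation_threshold=self.separation_threshold)
        bad = [t for t, f in out.fits.items() if f.flagged]
        if bad:
            return skipped("flagged fit in " + ", ".join(
                f"{t} ({out.fits[t].flag_reason})" for t in bad))

        for full_tag, red_tag in COMPARISONS:
            out.comparisons[f"{full_tag}_vs_{red_tag}"] = lrt(
                out.fits[full_tag], out.fits[red_tag])
        out.interaction_wald_p = out.fits["M1*M2"].wald_p(inter)
        for tag, f in out.fits.items():
            out.performance[tag] = roc_auc_delong(f.fitted_prob, y01)
        self.result_ = out
        self.fits_ = out.fits
        self.comparisons_ = out.comparisons
        self.auc_ = out.performance
        self.interaction_wald_p_ = out.interaction_wald_p
        self.n_used_ = out.n_used
        return self

    def predict_proba(self, cohort: Cohort) -> pd.Series:
        """Fitted response probabilities from the interaction model."""
        if getattr(self, "result_", None) is None or self.result_.status != "evaluated":
            raise ValueError("estimator not fitted or pair was skipped")
        m1, m2 = _as_spec(self.m1), _as_spec(self.m2)
        df = build_pair_design(cohort, m1, m2, list(self.covariates or []),
                               outcome="response")
        f = self.fits_["M1*M2"]
        cols = ["Intercept"] + f.covariate_names
        X = sm.add_constant(df[f.covariate_names], has_constant="add")
        X.columns = cols
        beta = np.array([f.coefficients[c] for c in cols])
        eta = X.to_numpy() @ beta
        return pd.Series(1 / (1 + np.exp(-eta)), index=df.index, name="prob")


def four_model_logit(cohort: Cohort, m1, m2, covariates=None,
                     **kwargs) -> FourModelFit:
    """Functional wrapper around :class:`DualMarkerLogit`."""
    return DualMarkerLogit(m1, m2, covariates, **kwargs).fit(cohort).result_
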