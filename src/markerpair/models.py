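"""Shared model-fit containers, the nested likelihood-ratio test, and the
design-matrix builder used by both the logistic and the Cox four-model
families.

The four-model family for a marker pair (M1, M2) is

    M1      outcome ~ M1 (+ covariates)
    M2      outcome ~ M2 (+ covariates)
    M1+M2   outcome ~ M1 + M2 (+ covariates)
    M1*M2   outcome ~ M1 + M2 + M1:M2 (+ covariates)

and the five nested comparisons are dual-vs-single (four) plus
interaction-vs-additive.  Covariates enter every model additively.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .cohort import Cohort, CohortError, MarkerSpec

MODEL_TAGS = ("M1", "M2", "M1+M2", "M1*M2")
COMPARISONS = (
    ("M1+M2", "M1"),
    ("M1*M2", "M1"),
    ("M1+M2", "M2"),
    ("M1*M2", "M2"),
    ("M1*M2", "M1+M2"),
)


@dataclass
class ModelFit:
    kind: str                      # "logit" | "cox"
    formula_tag: str               # "M1" | "M2" | "M1+M2" | "M1*M2" | custom
    coefficients: dict             # name -> estimate (includes "Intercept" for logit)
    se: dict
    loglik: float                  # maximized (partial) log-likelihood
    n_used: int
    converged: bool
    flagged: bool = False          # separation / monotone likelihood / other pathology
    flag_reason: str | None = None
    covariate_names: list = field(default_factory=list)
    linear_predictor: np.ndarray | None = None   # eta on the complete-case rows
    fitted_prob: np.ndarray | None = None        # logit only

    @property
    def n_params(self) -> int:
        return len(self.coefficients)

    def wald_p(self, name: str) -> float:
        """Two-sided normal-theory Wald p for one coefficient."""
        z = self.coefficients[name] / self.se[name]
        return float(2 * sps.norm.sf(abs(z)))

    def to_dict(self) -> dict:
        return {
            "kind": self.kind,
            "formula_tag": self.formula_tag,
            "coefficients": {k: float(v) for k, v in self.coefficients.items()},
            "se": {k: float(v) for k, v in self.se.items()},
            "loglik": float(self.loglik),
            "n_used": int(self.n_used),
            "converged": bool(self.converged),
            "flagged": bool(self.flagged),
            "flag_reason": self.flag_reason,
        }


@dataclass
class LRTResult:
    stat: float
    df: int
    p_value: float

    def to_dict(self) -> dict:
        return {"stat": float(self.stat), "df": int(self.df), "p_value": float(self.p_value)}


def lrt(full: ModelFit, reduced: ModelFit) -> LRTResult:
    """Likelihood-ratio test of nested fits: 2*(l_full - l_reduced) ~ chi2(df).

    Both fits must be of the same kind and computed on the identical
    complete-case set; a mismatch in ``n_used`` is a hard error because it
    would silently bias the comparison.
    """
    if full.kind != reduced.kind:
        raise ValueError("lrt: fits are of different kinds")
    if full.n_used != reduced.n_used:
        raise ValueError(
            f"lrt: n_used mismatch ({full.n_used} vs {reduced.n_used}); "
            "nested fits must share the complete-case set"
        )
    reduced_names = set(reduced.coefficients)
    if not reduced_names <= set(full.coefficients):
        raise ValueError("lrt: reduced model is not nested in the full model")
    df = full.n_params - reduced.n_params
    if df < 1:
        raise ValueError("lrt: full model must have more parameters than reduced")
    stat = max(0.0, 2.0 * (full.loglik - reduced.loglik))
    return LRTResult(stat, df, float(sps.chi2.sf(stat, df)))


@dataclass
class FourModelFit:
    kind: str
    m1_name: str
    m2_name: str
    fits: dict = field(default_factory=dict)          # tag -> ModelFit
    comparisons: dict = field(default_factory=dict)   # "full_vs_reduced" -> LRTResult
    interaction_wald_p: float | None = None
    performance: dict = field(default_factory=dict)   # tag -> AUCResult | CPEResult
    n_used: int = 0
    status: str = "evaluated"                         # "evaluated" | "skipped"
    skip_reason: str | None = None

    def comparison(self, full_tag: str, reduced_tag: str) -> LRTResult:
        return self.comparisons[f"{full_tag}_vs_{reduced_tag}"]

    def to_dict(self) -> dict:
        out = {
            "kind": self.kind,
            "m1": self.m1_name,
            "m2": self.m2_name,
            "status": self.status,
            "skip_reason": self.skip_reason,
            "n_used": int(self.n_used),
        }
        if self.status == "evaluated":
            out["fits"] = {t: f.to_dict() for t, f in self.fits.items()}
            out["comparisons"] = {k: v.to_dict() for k, v in self.comparisons.items()}
            out["interaction_wald_p"] = float(self.interaction_wald_p)
            out["performance"] = {t: p.to_dict() for t, p in self.performance.items()}
        return out


def _numeric_covariate(col: pd.Series) -> pd.Series:
    """Coerce a covariate to numeric; two-level string columns become 0/1."""
    num = pd.to_numeric(col, errors="coerce")
    if num.notna().sum() >= col.notna().sum():
        return num
    levels = sorted(col.dropna().astype(str).unique())
    if len(levels) != 2:
        raise CohortError(
            f"covariate {col.name!r} is non-numeric with {len(levels)} levels; "
            "ordinal/multi-level variables are unsupported"
        )
    out = pd.Series(np.nan, index=col.index, name=col.name)
    ok = col.notna()
    out[ok] = (col[ok].astype(str) == levels[1]).astype(float)
    return out


def build_pair_design(cohort: Cohort, m1: MarkerSpec, m2: MarkerSpec,
                      covariates=None, outcome: str = "response") -> pd.DataFrame:
    """Complete-case frame with outcome column(s), m1, m2, m1:m2 and covariates.

    Marker regressors are the raw continuous values or the 0/1 coding of a
    binary marker; the interaction column is their elementwise product.
    Rows with any missing value among the used columns are dropped
    (complete-case per pair; no imputation).
    """
    covariates = list(covariates or [])
    frame = {}
    if outcome == "response":
        if not cohort.has_response:
            raise CohortError("cohort has no response outcome")
        frame["response"] = cohort.data["response"]
    elif outcome == "survival":
        if not cohort.has_survival:
            raise CohortError("cohort has no survival outcome")
        frame["surv_time"] = cohort.data["surv_time"]
        frame["surv_event"] = cohort.data["surv_event"]
    else:
        raise ValueError(f"unknown outcome {outcome!r}")

    x1 = cohort.marker_values(m1)
    x2 = cohort.marker_values(m2)
    inter_name = f"{m1.name}:{m2.name}"
    frame[m1.name] = x1
    frame[m2.name] = x2
    frame[inter_name] = x1 * x2
    for cov in covariates:
        if cov not in cohort.data.columns:
            raise CohortError(f"covariate column {cov!r} not in cohort")
        frame[cov] = _numeric_covariate(cohort.data[cov])
    df = pd.DataFrame(frame).dropna()
    df.attrs["interaction"] = inter_name
    return df
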