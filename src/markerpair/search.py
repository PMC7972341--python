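"""De-novo biomarker-partner search.

For a fixed marker1, every candidate marker2 is scored by fitting the
four-model family and taking, against each single-marker model, the smaller
of the two dual-model LRT p-values (additive or interaction) — an
exploratory min-p rule.  Candidates are prioritized by the dual-vs-M1 p,
reported with a signed -log10 p whose sign encodes whether the candidate's
own single-marker effect is favorable (higher response odds, or longer
survival i.e. a negative Cox log-hazard coefficient), and BH-adjusted across
all evaluated candidates.  ``comb_m`` extends the same scoring to all
unordered marker pairs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .cohort import Cohort, MarkerSpec
from .cox import DualMarkerCox
from .logit import DualMarkerLogit
from .stats import bh_adjust

__all__ = ["SearchConfig", "MarkerPairSearch", "search_m2", "comb_m",
           "signed_log10_p"]


def signed_log10_p(p: float, direction: str, cap: float = 300.0) -> float:
    """-log10(p) signed +1 for a favorable, -1 for an unfavorable M2 effect.

    p = 0 (numerical underflow) is capped at ``cap``.
    """
    if direction not in ("favorable", "unfavorable"):
        raise ValueError(f"unknown direction {direction!r}")
    if not 0 <= p <= 1:
        raise ValueError("p out of [0,1]")
    mag = cap if p == 0 else min(cap, -np.log10(p))
    return float(mag if direction == "favorable" else -mag)


@dataclass
class SearchConfig:
    """Knobs of one search run."""
    family: str = "logit"                 # "logit" | "cox"
    covariates: list = field(default_factory=list)
    min_n: int = 20
    min_per_class: int = 5
    min_events: int = 10
    collinearity_r: float = 0.999
    alpha_lines: tuple = (0.01, 0.05)
    p_cap: float = 300.0

    def __post_init__(self):
        if self.family not in ("logit", "cox"):
            raise ValueError(f"unknown family {self.family!r}")

    def to_dict(self) -> dict:
        return {"family": self.family, "covariates": list(self.covariates),
                "min_n": self.min_n, "min_per_class": self.min_per_class,
                "min_events": self.min_events,
                "collinearity_r": self.collinearity_r,
                "alpha_lines": list(self.alpha_lines), "p_cap": self.p_cap}


def _as_spec(marker) -> MarkerSpec:
    return marker if isinstance(marker, MarkerSpec) else MarkerSpec(str(marker))


_SKIP_COLS = ["p_dual_vs_m1", "chosen_dual_vs_m1", "p_dual_vs_m2",
              "chosen_dual_vs_m2", "interaction_p", "m2_single_p",
              "m2_single_effect_direction", "signed_log10_p"]


class MarkerPairSearch(BaseEstimator):
    """Search biomarker partners (fixed M1) or score all pairs (M1 = None).

    Parameters
    ----------
    family : "logit" (binary response) or "cox" (survival).
    m1 : fixed marker1 (name or spec), or None to evaluate every unordered
        candidate pair with the lexicographically first name as M1.
    candidates : candidate marker names/specs; defaults to every marker
        column of the cohort (minus m1).
    config : :class:`SearchConfig`; keyword arguments above override it.

    Attributes (after ``fit``)
    --------------------------
    results_ : DataFrame, one row per candidate (or pair), sorted by
        ``p_dual_vs_m1`` ascending with skipped rows last; BH-adjusted
        columns computed across evaluated rows only.
    """

    def __init__(self, family: str = "logit", m1=None, candidates=None,
                 covariates=None, min_n: int = 20, min_per_class: int = 5,
                 min_events: int = 10, collinearity_r: float = 0.999,
                 p_cap: float = 300.0):
        self.family = family
        self.m1 = m1
        self.candidates = candidates
        self.covariates = covariates
        self.min_n = min_n
        self.min_per_class = min_per_class
        self.min_events = min_events
        self.collinearity_r = collinearity_r
        self.p_cap = p_cap

    def _pair_estimator(self, s1: MarkerSpec, s2: MarkerSpec):
        if self.family == "logit":
            return DualMarkerLogit(s1, s2, self.covariates, min_n=self.min_n,
                                   min_per_class=self.min_per_class,
                                   collinearity_r=self.collinearity_r)
        if self.family == "cox":
            return DualMarkerCox(s1, s2, self.covariates, min_n=self.min_n,
                                 min_events=self.min_events,
                                 collinearity_r=self.collinearity_r)
        raise ValueError(f"unknown family {self.family!r}")

    def _row(self, cohort: Cohort, s1: MarkerSpec, s2: MarkerSpec) -> dict:
        fm = self._pair_estimator(s1, s2).fit(cohort).result_
        row = {"m1": s1.name, "m2": s2.name, "status": fm.status,
               "reason": fm.skip_reason, "n_used": fm.n_used}
        if fm.status != "evaluated":
            row.update({c: np.nan for c in _SKIP_COLS})
            return row
        for target, key in (("m1", "M1"), ("m2", "M2")):
            p_add = fm.comparison("M1+M2", key).p_value
            p_int = fm.comparison("M1*M2", key).p_value
            row[f"p_dual_vs_{target}"] = min(p_add, p_int)
            row[f"chosen_dual_vs_{target}"] = (
                "additive" if p_add <= p_int else "interaction")
        row["interaction_p"] = fm.interaction_wald_p
        m2fit = fm.fits["M2"]
        coef = m2fit.coefficients[s2.name]
        favorable = coef > 0 if self.family == "logit" else coef < 0
        row["m2_single_effect_direction"] = ("favorable" if favorable
                                             else "unfavorable")
        row["m2_single_p"] = m2fit.wald_p(s2.name)
        row["signed_log10_p"] = signed_log10_p(
            row["p_dual_vs_m1"], row["m2_single_effect_direction"],
            cap=self.p_cap)
        metric = "auc" if self.family == "logit" else "cpe"
        for tag, perf in fm.performance.items():
            row[f"{metric}_{tag}"] = getattr(perf, metric)
        return row

    def fit(self, cohort: Cohort, y=None):
        cands = [_as_spec(c) for c in (self.candidates or cohort.markers)]
        if self.m1 is not None:
            s1 = _as_spec(self.m1)
            pairs = [(s1, c) for c in cands if c.name != s1.name]
        else:
            cands = sorted(cands, key=lambda s: s.name)
            pairs = [(a, b) for i, a in enumerate(cands)
                     for b in cands[i + 1:]]
            if len(pairs) == 0:
                raise ValueError("comb_m mode needs at least 2 candidates")
        rows = [self._row(cohort, a, b) for a, b in pairs]
        df = pd.DataFrame(rows)
        evaluated = df["status"] == "evaluated"
        for col in ("p_dual_vs_m1", "p_dual_vs_m2"):
            adj = pd.Series(np.nan, index=df.index)
            if evaluated.any():
                adj[evaluated] = bh_adjust(df.loc[evaluated, col].to_numpy())
            df[f"adj_{col}"] = adj
        df = df.sort_values(["p_dual_vs_m1", "m1", "m2"],
                            na_position="last", kind="mergesort")
        self.results_ = df.reset_index(drop=True)
        self.n_evaluated_ = int(evaluated.sum())
        self.n_skipped_ = int((~evaluated).sum())
        return self


def search_m2(cohort: Cohort, m1, candidates=None,
              config: SearchConfig | None = None, **kwargs) -> pd.DataFrame:
    """Score candidate marker2s against a fixed marker1; see
    :class:`MarkerPairSearch`."""
    cfg = config or SearchConfig(**kwargs) if (config or kwargs) else SearchConfig()
    est = MarkerPairSearch(cfg.family, m1=m1, candidates=candidates,
                           covariates=cfg.covariates, min_n=cfg.min_n,
                           min_per_class=cfg.min_per_class,
                           min_events=cfg.min_events,
                           collinearity_r=cfg.collinearity_r, p_cap=cfg.p_cap)
    return est.fit(cohort).results_


def comb_m(cohort: Cohort, candidates=None,
           config: SearchConfig | None = None, **kwargs) -> pd.DataFrame:
    """Score all unordered candidate pairs; see :class:`MarkerPairSearch`."""
    cfg = config or SearchConfig(**kwargs) if (config or kwargs) else SearchConfig()
    est = MarkerPairSearch(cfg.family, m1=None, candidates=candidates,
                           covariates=cfg.covariates, min_n=cfg.min_n,
                           min_per_class=cfg.min_per_class,
                           min_events=cfg.min_events,
                           collinearity_r=cfg.collinearity_r, p_cap=cfg.p_cap)
    return est.fit(cohort).results_
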