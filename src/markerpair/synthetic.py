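"""Synthetic clinical cohorts with known logistic and proportional-hazards
structure.

The generator emulates an immunotherapy-trial biomarker table: a few hundred
patients, a binary response drawn from a logistic model on two markers (with
optional marker-marker interaction and covariates), and an overall-survival
outcome drawn from an exponential proportional-hazards model with
independent exponential censoring plus an administrative cutoff.  Decoy
markers are independent standard normals, giving a clean null for search
benchmarks.  Every draw is fully determined by the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import Cohort

__all__ = ["SimConfig", "simulate_cohort", "simulate_search_panel"]


@dataclass
class SimConfig:
    """Generating model for one synthetic cohort.

    Defaults sketch a mid-sized trial cohort: n = 300 patients, ~30%
    responders, a moderately favorable marker1 and unfavorable marker2,
    a baseline exponential hazard of 0.08 events/month (median OS ~ 8.7
    months), exponential censoring at 0.03/month plus administrative
    follow-up cutoff at 24 months (~30-35% censored overall).

    marker distributions are ``("normal", mu, sigma)``,
    ``("lognormal", mu, sigma)`` or ``("bernoulli", p)``.
    """
    n: int = 300
    seed: int = 0
    m1_dist: tuple = ("normal", 0.0, 1.0)
    m2_dist: tuple = ("normal", 0.0, 1.0)
    # logistic response model: logit P(resp) = b0 + b1 m1 + b2 m2 + b12 m1 m2
    b0: float = -1.0
    b1: float = 0.8
    b2: float = -0.6
    b12: float = 0.0
    # exponential PH survival model: hazard = lambda0 * exp(g1 m1 + g2 m2 + g12 m1 m2)
    lambda0: float = 0.08
    g1: float = -0.5
    g2: float = 0.3
    g12: float = 0.0
    censor_rate: float = 0.03
    admin_tau: float = 24.0
    n_decoy: int = 0
    # standard-normal covariates: name -> (effect on response lp, on log-hazard)
    covariate_effects: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if self.lambda0 <= 0:
            raise ValueError("baseline hazard must be > 0")
        if self.censor_rate < 0:
            raise ValueError("censoring rate must be >= 0")


def _draw(rng: np.random.Generator, dist: tuple, n: int) -> np.ndarray:
    kind = dist[0]
    if kind == "normal":
        return rng.normal(dist[1], dist[2], n)
    if kind == "lognormal":
        return rng.lognormal(dist[1], dist[2], n)
    if kind == "bernoulli":
        p = dist[1]
        if not 0 <= p <= 1:
            raise ValueError("bernoulli p out of [0,1]")
        return rng.binomial(1, p, n).astype(float)
    raise ValueError(f"unknown marker distribution {kind!r}")


def _outcomes(rng, cfg: SimConfig, lp_resp, lp_surv, n):
    response = rng.binomial(1, 1.0 / (1.0 + np.exp(-lp_resp))).astype(float)
    rate = cfg.lambda0 * np.exp(lp_surv)
    t_event = rng.exponential(1.0 / rate)
    if cfg.censor_rate > 0:
        t_cens = rng.exponential(1.0 / cfg.censor_rate, n)
    else:
        t_cens = np.full(n, np.inf)
    if np.isfinite(cfg.admin_tau):
        t_cens = np.minimum(t_cens, cfg.admin_tau)
    time = np.minimum(t_event, t_cens)
    event = (t_event <= t_cens).astype(float)
    return response, time, event


def _assemble(cfg: SimConfig, columns: dict, markers: list, covs: list) -> Cohort:
    ids = [f"S{i + 1:04d}" for i in range(cfg.n)]
    df = pd.DataFrame(columns, index=pd.Index(ids, name="sample_id"))
    return Cohort(df, markers, covs, has_response=True, has_survival=True)


def simulate_cohort(config: SimConfig) -> Cohort:
    """Draw one cohort with markers m1, m2 (+ optional decoys/covariates)."""
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n
    x1 = _draw(rng, cfg.m1_dist, n)
    x2 = _draw(rng, cfg.m2_dist, n)
    covs = {name: rng.normal(size=n) for name in cfg.covariate_effects}
    lp_resp = cfg.b0 + cfg.b1 * x1 + cfg.b2 * x2 + cfg.b12 * x1 * x2
    lp_surv = cfg.g1 * x1 + cfg.g2 * x2 + cfg.g12 * x1 * x2
    for name, (br, gs) in cfg.covariate_effects.items():
        lp_resp = lp_resp + br * covs[name]
        lp_surv = lp_surv + gs * covs[name]
    response, time, event = _outcomes(rng, cfg, lp_resp, lp_surv, n)
    columns = {"response": response, "surv_time": time, "surv_event": event,
               "m1": x1, "m2": x2}
    markers = ["m1", "m2"]
    for k in range(cfg.n_decoy):
        name = f"decoy_{k + 1:03d}"
        columns[name] = rng.normal(size=n)
        markers.append(name)
    columns.update(covs)
    return _assemble(cfg, columns, markers, list(covs))


def simulate_search_panel(config: SimConfig, n_true: int = 1) -> tuple:
    """Cohort for search benchmarks: marker m1 plus a candidate panel of
    ``n_true`` true additive partners (effects b2 on the response scale and
    g2 on the log-hazard scale) and ``config.n_decoy`` null decoys.

    Returns ``(cohort, truth)`` where truth maps candidate name -> bool.
    """
    cfg = config
    if n_true > cfg.n_decoy + n_true:
        raise ValueError("n_true exceeds panel size")
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n
    x1 = _draw(rng, cfg.m1_dist, n)
    trues = {f"true_{k + 1:03d}": _draw(rng, cfg.m2_dist, n)
             for k in range(n_true)}
    decoys = {f"decoy_{k + 1:03d}": rng.normal(size=n)
              for k in range(cfg.n_decoy)}
    lp_resp = cfg.b0 + cfg.b1 * x1
    lp_surv = cfg.g1 * x1
    for xt in trues.values():
        lp_resp = lp_resp + cfg.b2 * xt + cfg.b12 * x1 * xt
        lp_surv = lp_surv + cfg.g2 * xt + cfg.g12 * x1 * xt
    response, time, event = _outcomes(rng, cfg, lp_resp, lp_surv, n)
    columns = {"response": response, "surv_time": time, "surv_event": event,
               "m1": x1, **trues, **decoys}
    markers = ["m1"] + list(trues) + list(decoys)
    cohort = _assemble(cfg, columns, markers, [])
    truth = {name: name in trues for name in list(trues) + list(decoys)}
    return cohort, truth
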