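"""Pair report: every statistic behind the plot bundle for one marker pair,
plus matplotlib rendering.

The report computes plot-ready data structures first (boxplot groups, ROC
points, quadrant statistics, KM curves, conditional KM comparisons, the two
four-model fits); rendering is side-effect-only drawing of those structures,
so every number shown in a figure is reproducible from the serialized
statistics file alone.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import (Cohort, CohortError, MarkerSpec, QUADRANT_COLORS,
                     QUADRANTS, assign_quadrants, dichotomize)
from .cox import (conditional_km, four_model_cox, km_estimate, logrank_test,
                  quadrant_survival_stats)
from .logit import four_model_logit, roc_auc_delong
from .stats import binomial_ci, fisher_exact_2x2, spearman_corr, wilcoxon_rank_sum

__all__ = ["PairReport", "build_pair_report", "render", "write_stats_json"]

#: response-rate line chart / quadrant layout: R-label by (M1 level, M2 level)
_QUAD_BY_LEVELS = {("high", "high"): "R1", ("low", "high"): "R2",
                   ("low", "low"): "R3", ("high", "low"): "R4"}


@dataclass
class PairReport:
    m1_name: str
    m2_name: str
    cutpoints: dict
    response_section: dict | None
    survival_section: dict | None
    model_section: dict

    def to_dict(self) -> dict:
        return {"m1": self.m1_name, "m2": self.m2_name,
                "cutpoints": self.cutpoints,
                "response": self.response_section,
                "survival": self.survival_section,
                "models": self.model_section}


def _san(obj):
    """JSON-ready copy: numpy scalars to python, NaN/inf to None."""
    if isinstance(obj, dict):
        return {str(k): _san(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_san(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return [_san(v) for v in obj.tolist()]
    if isinstance(obj, (np.floating, float)):
        return float(obj) if np.isfinite(obj) else None
    if isinstance(obj, (np.integer, int)):
        return int(obj)
    if isinstance(obj, (np.bool_, bool)):
        return bool(obj)
    return obj


def _curve_dict(curve) -> dict:
    return {"time": curve.event_times, "n_at_risk": curve.n_at_risk,
            "n_events": curve.n_events, "survival": curve.survival,
            "ci_low": curve.ci_low, "ci_high": curve.ci_high,
            "median": curve.median,
            "median_ci": list(curve.median_ci), "n": curve.n,
            "n_observed_events": curve.n_observed_events}


def _roc_points(scores, labels):
    from sklearn.metrics import roc_curve
    fpr, tpr, _ = roc_curve(labels, scores)
    return fpr, tpr


def _response_section(cohort, m1, m2, lev1, lev2, fm) -> dict:
    df = pd.DataFrame({
        "response": cohort.data["response"],
        m1.name: cohort.marker_values(m1),
        m2.name: cohort.marker_values(m2),
        "lev1": lev1, "lev2": lev2,
    })
    sec: dict = {}
    box = {}
    for spec, col in ((m1, m1.name), (m2, m2.name)):
        sub = df[["response", col]].dropna()
        grp_r = sub.loc[sub["response"] == 1, col].to_numpy()
        grp_n = sub.loc[sub["response"] == 0, col].to_numpy()
        entry = {"responder": grp_r, "non_responder": grp_n}
        if grp_r.size and grp_n.size:
            entry["wilcoxon"] = wilcoxon_rank_sum(grp_r, grp_n).to_dict()
        box[col] = entry
    sec["boxplots"] = box

    sc = df[[m1.name, m2.name, "response"]].dropna()
    sec["scatter"] = {
        "x_name": m1.name, "y_name": m2.name,
        "x": sc[m1.name].to_numpy(), "y": sc[m2.name].to_numpy(),
        "response": sc["response"].to_numpy(),
        "spearman": spearman_corr(sc[m1.name], sc[m2.name]).to_dict()
        if len(sc) >= 3 else None,
    }

    qdf = df[["response", "lev1", "lev2"]].dropna()
    qa = assign_quadrants(qdf["lev1"], qdf["lev2"],
                          high=m1.label_high, low=m1.label_low)
    qdf = qdf.assign(quadrant=qa.quadrant)
    table = [[qa.counts["R1"], qa.counts["R4"]],
             [qa.counts["R2"], qa.counts["R3"]]]
    rates = {}
    for q in QUADRANTS:
        sub = qdf[qdf["quadrant"] == q]
        if len(sub):
            rates[q] = binomial_ci(int(sub["response"].sum()), len(sub)).to_dict()
        else:
            rates[q] = None
    total = max(1, qa.n_complete)
    sec["quadrants"] = {
        "counts": qa.counts, "n_excluded_missing": qa.n_excluded_missing,
        "fisher": fisher_exact_2x2(table).to_dict(),
        "rates": rates,
        "doughnut": {q: {"size_fraction": qa.counts[q] / total,
                         "rate": rates[q]["rate"] if rates[q] else None}
                     for q in QUADRANTS},
    }
    lines = {}
    for m2lev in ("high", "low"):
        pts = []
        for m1lev in ("low", "high"):
            q = _QUAD_BY_LEVELS[(m1lev, m2lev)]
            pts.append(rates[q]["rate"] if rates[q] else None)
        lines[f"{m2.name} {m2lev}"] = pts
    sec["line_chart"] = {"x_name": m1.name, "x_levels": ["low", "high"],
                         "y": "response_rate", "lines": lines}

    roc = {}
    if fm is not None and fm.status == "evaluated":
        labels = fm._labels  # shared complete-case response, set by build_pair_report
        for tag, f in fm.fits.items():
            fpr, tpr = _roc_points(f.fitted_prob, labels)
            roc[tag] = {"auc": fm.performance[tag].to_dict(),
                        "fpr": fpr, "tpr": tpr}
    sec["roc"] = roc
    return sec


def _survival_section(cohort, m1, m2) -> dict:
    sec: dict = {}
    km_single = {}
    for spec in (m1, m2):
        lev = dichotomize(cohort.data[spec.name], spec).levels
        sub = pd.DataFrame({"time": cohort.data["surv_time"],
                            "event": cohort.data["surv_event"],
                            "lev": lev}).dropna()
        entry = {"levels": {}}
        for l in (spec.label_high, spec.label_low):
            s = sub[sub["lev"] == l]
            if len(s):
                entry["levels"][l] = _curve_dict(km_estimate(s["time"], s["event"]))
        if sub["lev"].nunique() >= 2 and sub["event"].sum() >= 1:
            entry["logrank"] = logrank_test(sub["time"], sub["event"],
                                            sub["lev"]).to_dict()
        km_single[spec.name] = entry
    sec["km_single"] = km_single

    qs = quadrant_survival_stats(cohort, m1, m2)
    sec["km_quadrants"] = {
        "curves": {q: _curve_dict(c) for q, c in qs.curves.items()},
        "logrank": qs.logrank.to_dict() if qs.logrank else None,
    }
    sec["quadrant_stats"] = {
        "counts": qs.counts,
        "medians": qs.medians,
        "median_cis": {q: list(ci) for q, ci in qs.median_cis.items()},
        "fisher": qs.fisher.to_dict(),
    }
    lines = {}
    for m2lev in ("high", "low"):
        pts = []
        for m1lev in ("low", "high"):
            q = _QUAD_BY_LEVELS[(m1lev, m2lev)]
            pts.append(qs.medians.get(q))
        lines[f"{m2.name} {m2lev}"] = pts
    sec["line_chart"] = {"x_name": m1.name, "x_levels": ["low", "high"],
                         "y": "median_survival", "lines": lines}

    ckm = conditional_km(cohort, m1, m2)
    cond = {}
    for key, entry in ckm.entries.items():
        e = {"evaluable": entry["evaluable"], "n": entry["n"]}
        if entry["evaluable"]:
            e["p_value"] = entry["p_value"]
            e["p_adjusted"] = entry["p_adjusted"]
            e["curves"] = {l: _curve_dict(c) for l, c in entry["curves"].items()}
        else:
            e["reason"] = entry.get("reason")
        cond[key] = e
    sec["conditional_km"] = cond
    return sec


def build_pair_report(cohort: Cohort, m1, m2, covariates=None,
                      **model_kwargs) -> PairReport:
    """Compute all plot-ready statistics for one marker pair.

    The response section is present iff the cohort has a binary response,
    the survival section iff it has survival columns; a cohort with neither
    is rejected at load time already.
    """
    m1 = m1 if isinstance(m1, MarkerSpec) else MarkerSpec(str(m1))
    m2 = m2 if isinstance(m2, MarkerSpec) else MarkerSpec(str(m2))
    if not (cohort.has_response or cohort.has_survival):
        raise CohortError("neither response nor survival outcome present")
    d1 = dichotomize(cohort.data[m1.name], m1)
    d2 = dichotomize(cohort.data[m2.name], m2)
    cutpoints = {m1.name: d1.cutpoint, m2.name: d2.cutpoint}

    models: dict = {"logit": None, "cox": None}
    resp_sec = None
    if cohort.has_response:
        fm = four_model_logit(cohort, m1, m2, covariates, **model_kwargs)
        if fm.status == "evaluated":
            # labels on the shared complete-case set, for ROC points
            from .models import build_pair_design
            dd = build_pair_design(cohort, m1, m2, covariates, "response")
            fm._labels = dd["response"].to_numpy()
        models["logit"] = fm
        resp_sec = _response_section(cohort, m1, m2, d1.levels, d2.levels, fm)
    surv_sec = None
    if cohort.has_survival:
        models["cox"] = four_model_cox(cohort, m1, m2, covariates, **model_kwargs)
        surv_sec = _survival_section(cohort, m1, m2)
    model_section = {k: (v.to_dict() if v is not None else None)
                     for k, v in models.items()}
    return PairReport(m1.name, m2.name, cutpoints, resp_sec, surv_sec,
                      model_section)


def write_stats_json(report: PairReport, path) -> None:
    """Serialize the full report deterministically (sorted keys)."""
    payload = _san(report.to_dict())
    Path(path).write_text(json.dumps(payload, sort_keys=True, indent=1) + "\n")


# ---------------------------------------------------------------------------
# rendering (drawing only; no statistics computed here)

def _step(ax, curve: dict, label, color=None):
    t = np.concatenate([[0.0], np.asarray(curve["time"], dtype=float)])
    s = np.concatenate([[1.0], np.asarray(curve["survival"], dtype=float)])
    ax.step(t, s, where="post", label=str(label), color=color)


def render(report: PairReport, out_dir, fmt: str = "png") -> dict:
    """Render every figure of the report plus the stats JSON.

    Returns a manifest mapping entry name -> file name; the manifest itself
    is written as ``manifest.json``.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if fmt not in ("png", "svg", "pdf"):
        raise ValueError(f"unsupported figure format {fmt!r}")
    manifest: dict = {}

    def save(fig, name):
        fname = f"{name}.{fmt}"
        fig.savefig(out / fname, dpi=100)
        plt.close(fig)
        manifest[name] = fname

    rs = report.response_section
    if rs:
        for i, (mname, entry) in enumerate(rs["boxplots"].items(), 1):
            fig, ax = plt.subplots(figsize=(4, 4))
            data = [entry["non_responder"], entry["responder"]]
            ax.boxplot(data, tick_labels=["non-resp", "resp"])
            for j, vals in enumerate(data, 1):
                ax.plot(np.full(len(vals), j), vals, "o", alpha=0.4, ms=3)
            w = entry.get("wilcoxon")
            ax.set_title(f"{mname}" + (f"  Wilcoxon p={w['p_value']:.3g}" if w else ""))
            save(fig, f"response_boxplot_m{i}")
        sc = rs["scatter"]
        fig, ax = plt.subplots(figsize=(4.5, 4))
        resp = np.asarray(sc["response"])
        for val, col, lab in ((0, "grey", "non-resp"), (1, "crimson", "resp")):
            sel = resp == val
            ax.plot(np.asarray(sc["x"])[sel], np.asarray(sc["y"])[sel], "o",
                    color=col, ms=4, alpha=0.6, label=lab)
        if sc["spearman"]:
            ax.set_title(f"Spearman rho={sc['spearman']['estimate']:.2f} "
                         f"p={sc['spearman']['p_value']:.3g}")
        ax.set_xlabel(sc["x_name"]); ax.set_ylabel(sc["y_name"]); ax.legend()
        save(fig, "response_scatter")
        fig, ax = plt.subplots(figsize=(4.5, 4))
        for tag, r in rs["roc"].items():
            ax.plot(r["fpr"], r["tpr"],
                    label=f"{tag} AUC={r['auc']['auc']:.3f}")
        ax.plot([0, 1], [0, 1], "k:", lw=0.8)
        ax.set_xlabel("1 - specificity"); ax.set_ylabel("sensitivity")
        ax.legend(fontsize=7)
        save(fig, "response_roc")
        save(_area_proportion(plt, report, rs["quadrants"]), "response_area_proportion")
        save(_quadrant_matrix(plt, report, rs["quadrants"], mode="response"),
             "response_quadrant_matrix")
        save(_doughnut(plt, rs["quadrants"]), "response_doughnut")
        save(_line_chart(plt, rs["line_chart"]), "response_line_chart")

    ss = report.survival_section
    if ss:
        for i, (mname, entry) in enumerate(ss["km_single"].items(), 1):
            fig, ax = plt.subplots(figsize=(4.5, 4))
            for lab, curve in entry["levels"].items():
                _step(ax, curve, f"{mname} {lab}")
            lr = entry.get("logrank")
            ax.set_title(f"log-rank p={lr['p_value']:.3g}" if lr else mname)
            ax.set_xlabel("time"); ax.set_ylabel("survival"); ax.legend(fontsize=8)
            save(fig, f"surv_km_m{i}")
        fig, ax = plt.subplots(figsize=(4.5, 4))
        for q, curve in ss["km_quadrants"]["curves"].items():
            _step(ax, curve, q, color=QUADRANT_COLORS[q])
        lr = ss["km_quadrants"]["logrank"]
        ax.set_title(f"log-rank p={lr['p_value']:.3g}" if lr else "")
        ax.set_xlabel("time"); ax.set_ylabel("survival"); ax.legend(fontsize=8)
        save(fig, "surv_km_quadrants")
        save(_area_proportion(plt, report, ss["quadrant_stats"]),
             "surv_area_proportion")
        save(_quadrant_matrix(plt, report, ss["quadrant_stats"], mode="survival"),
             "surv_quadrant_matrix")
        save(_line_chart(plt, ss["line_chart"]), "surv_line_chart")
        fig, axes = plt.subplots(2, 2, figsize=(8, 7))
        for ax, (key, entry) in zip(axes.ravel(), ss["conditional_km"].items()):
            ax.set_title(key, fontsize=8)
            if entry["evaluable"]:
                for lab, curve in entry["curves"].items():
                    _step(ax, curve, lab)
                ax.text(0.55, 0.9, f"p={entry['p_value']:.3g}\n"
                        f"adj p={entry['p_adjusted']:.3g}",
                        transform=ax.transAxes, fontsize=7)
                ax.legend(fontsize=6)
            else:
                ax.text(0.5, 0.5, "not evaluable", ha="center",
                        transform=ax.transAxes)
        fig.tight_layout()
        save(fig, "surv_km_conditional")

    write_stats_json(report, out / "stats.json")
    manifest["stats"] = "stats.json"
    (out / "manifest.json").write_text(
        json.dumps(manifest, sort_keys=True, indent=1) + "\n")
    return manifest


def _area_proportion(plt, report, qstats):
    """Mosaic-style chart: quadrant rectangles proportional to group size."""
    counts = qstats["counts"]
    total = max(1, sum(counts.values()))
    # column widths from the M1 margin, heights from M2 share within column
    w_high = (counts["R1"] + counts["R4"]) / total
    fig, ax = plt.subplots(figsize=(4.5, 4))
    layout = {"R1": (1 - w_high, "high"), "R4": (1 - w_high, "low"),
              "R2": (0.0, "high"), "R3": (0.0, "low")}
    for q in QUADRANTS:
        x0, band = layout[q]
        w = w_high if q in ("R1", "R4") else 1 - w_high
        col_total = (counts["R1"] + counts["R4"]) if q in ("R1", "R4") \
            else (counts["R2"] + counts["R3"])
        h = counts[q] / col_total if col_total else 0.0
        y0 = 1 - h if band == "high" else 0.0
        ax.add_patch(plt.Rectangle((x0, y0), w, h, color=QUADRANT_COLORS[q],
                                   alpha=0.75))
        if w * h > 0:
            ax.text(x0 + w / 2, y0 + h / 2, f"{q}\nn={counts[q]}",
                    ha="center", va="center", fontsize=8)
    f = qstats["fisher"]
    ax.set_title(f"Fisher p={f['p_value']:.3g}")
    ax.set_xlabel(f"{report.m1_name} (low | high)")
    ax.set_ylabel(f"{report.m2_name} (low on bottom)")
    ax.set_xlim(0, 1); ax.set_ylim(0, 1)
    return fig


def _quadrant_matrix(plt, report, qstats, mode):
    fig, ax = plt.subplots(figsize=(4.5, 4))
    pos = {"R1": (1, 1), "R2": (0, 1), "R3": (0, 0), "R4": (1, 0)}
    for q, (x, y) in pos.items():
        ax.add_patch(plt.Rectangle((x, y), 1, 1, fill=True,
                                   color=QUADRANT_COLORS[q], alpha=0.25))
        n = qstats["counts"][q]
        if mode == "response":
            r = qstats["rates"][q]
            txt = (f"{q}\nn={n}\nrate={r['rate']:.2f}\n"
                   f"CI {r['ci_low']:.2f}-{r['ci_high']:.2f}") if r else f"{q}\nn={n}"
        else:
            med = qstats["medians"].get(q)
            lo, hi = qstats["median_cis"].get(q, (None, None))
            fmtv = lambda v: "NA" if v is None else f"{v:.3g}"
            txt = f"{q}\nn={n}\nmedian={fmtv(med)}\nCI {fmtv(lo)}-{fmtv(hi)}"
        ax.text(x + 0.5, y + 0.5, txt, ha="center", va="center", fontsize=8)
    ax.set_xlim(0, 2); ax.set_ylim(0, 2); ax.set_xticks([]); ax.set_yticks([])
    ax.set_xlabel(f"{report.m1_name}: low | high")
    ax.set_ylabel(f"{report.m2_name}: low | high")
    return fig


def _doughnut(plt, qstats):
    fig, ax = plt.subplots(figsize=(4.5, 4))
    theta = 90.0
    for q in QUADRANTS:
        d = qstats["doughnut"][q]
        frac = d["size_fraction"]
        if frac <= 0:
            continue
        sweep = 360.0 * frac
        width = 0.15 + 0.25 * frac          # ring width encodes group size
        rate = d["rate"] or 0.0
        import matplotlib.patches as mpatches
        # full wedge = group; colored arc fraction = response rate
        ax.add_patch(mpatches.Wedge((0, 0), 1.0, theta - sweep, theta,
                                    width=width, color="lightgrey"))
        ax.add_patch(mpatches.Wedge((0, 0), 1.0, theta - sweep * rate, theta,
                                    width=width, color=QUADRANT_COLORS[q]))
        mid = np.deg2rad(theta - sweep / 2)
        ax.text(1.12 * np.cos(mid), 1.12 * np.sin(mid), q, ha="center",
                va="center", fontsize=9)
        theta -= sweep
    ax.set_xlim(-1.3, 1.3); ax.set_ylim(-1.3, 1.3); ax.set_aspect("equal")
    ax.axis("off")
    return fig


def _line_chart(plt, lc):
    fig, ax = plt.subplots(figsize=(4.5, 4))
    x = [0, 1]
    for lab, pts in lc["lines"].items():
        xs = [xi for xi, p in zip(x, pts) if p is not None]
        ys = [p for p in pts if p is not None]
        ax.plot(xs, ys, "o-", label=lab)
    ax.set_xticks(x, [f"{lc['x_name']} {l}" for l in lc["x_levels"]])
    ax.set_ylabel(lc["y"])
    ax.legend(fontsize=8)
    return fig
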