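"""Patient-table data model: marker typing, dichotomization, quadrant assignment.

A :class:`Cohort` is one row per patient with an optional binary response,
optional right-censored survival outcome (time + event flag), and any number
of marker and covariate columns.  Markers are either continuous (entered raw
into the regression models) or binary (coded 0/1 via a declared positive
level).  For visualization and quadrant statistics both markers of a pair are
dichotomized into high/low and each complete case falls into one of four
quadrants:

    R1 = (M1 high, M2 high)   R2 = (M1 low, M2 high)
    R4 = (M1 high, M2 low)    R3 = (M1 low, M2 low)
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

QUADRANTS = ("R1", "R2", "R3", "R4")

#: fixed quadrant palette used by every plot of one report
QUADRANT_COLORS = {"R1": "#E64B35", "R2": "#4DBBD5", "R3": "#00A087", "R4": "#3C5488"}

MISSING_TOKENS = {"", "NA", "na", "NaN", "nan", "N/A"}


class CohortError(ValueError):
    """Raised on validation failure while building or using a Cohort."""


@dataclass
class MarkerSpec:
    """How one marker column is interpreted and dichotomized.

    Parameters
    ----------
    name : column name in the cohort table.
    kind : ``"continuous"`` or ``"binary"``.
    cutoff : for continuous markers, ``"median"`` (population median of the
        non-missing values) or an explicit numeric cutpoint.  Ignored for
        binary markers.
    positive_level : for binary markers, the observed level coded as
        positive/high (becomes the 0/1 regressor's 1).
    strict : if True (default) a continuous value is "high" iff strictly
        greater than the cutpoint; if False, greater-or-equal.
    """

    name: str
    kind: str = "continuous"
    cutoff: object = "median"
    positive_level: object = None
    label_high: str = "high"
    label_low: str = "low"
    strict: bool = True

    def __post_init__(self):
        if self.kind not in ("continuous", "binary"):
            raise CohortError(f"marker {self.name!r}: kind must be 'continuous' or 'binary'")


@dataclass
class DichotomizeResult:
    levels: pd.Series          # "high"/"low", NaN propagated as missing
    cutpoint: float | None     # realized numeric cutpoint (continuous only)


@dataclass
class QuadrantAssignment:
    quadrant: pd.Series                     # "R1".."R4" per sample, NaN if either level missing
    counts: dict = field(default_factory=dict)   # n per quadrant
    n_excluded_missing: int = 0

    @property
    def n_complete(self) -> int:
        return int(sum(self.counts.values()))


@dataclass
class Cohort:
    """Validated patient table.

    Attributes
    ----------
    data : DataFrame indexed by sample id with canonical columns
        ``response`` (0/1 float, NaN allowed), ``surv_time``, ``surv_event``
        plus the marker and covariate columns under their original names.
    markers, covariates : names of the marker / covariate columns.
    """

    data: pd.DataFrame
    markers: list
    covariates: list
    has_response: bool = False
    has_survival: bool = False
    load_report: dict = field(default_factory=dict)

    def __post_init__(self):
        if not self.data.index.is_unique:
            dup = self.data.index[self.data.index.duplicated()][0]
            raise CohortError(f"duplicate sample_id {dup!r}")
        if self.has_survival:
            t = self.data["surv_time"]
            e = self.data["surv_event"]
            bad = self.data.index[(t < 0) & e.notna()]
            if len(bad):
                raise CohortError(f"negative surv_time in row(s) {list(map(str, bad[:5]))}")
            lev = set(e.dropna().unique())
            if not lev <= {0, 1}:
                raise CohortError(f"surv_event must be 0/1, saw {sorted(lev)}")
        if self.has_response:
            lev = set(self.data["response"].dropna().unique())
            if not lev <= {0.0, 1.0}:
                raise CohortError(f"internal response coding must be 0/1, saw {sorted(lev)}")
        if not (self.has_response or self.has_survival):
            raise CohortError("cohort has neither a response nor a survival outcome")

    @property
    def n(self) -> int:
        return len(self.data)

    def marker_values(self, spec: MarkerSpec) -> pd.Series:
        """Numeric regressor column for a marker (binary markers coded 0/1)."""
        if spec.name not in self.data.columns:
            raise CohortError(f"marker column {spec.name!r} not in cohort")
        col = self.data[spec.name]
        if spec.kind == "binary":
            observed = set(col.dropna().unique())
            if len(observed) > 2:
                raise CohortError(
                    f"binary marker {spec.name!r} has {len(observed)} levels; "
                    "ordinal/multi-level variables are unsupported"
                )
            pos = spec.positive_level
            if pos is None:
                if observed <= {0, 1}:
                    pos = 1
                else:
                    raise CohortError(f"binary marker {spec.name!r} needs positive_level")
            if pos not in observed:
                raise CohortError(
                    f"positive_level {pos!r} not among observed levels of {spec.name!r}"
                )
            out = pd.Series(np.where(col.isna(), np.nan, (col == pos).astype(float)),
                            index=col.index, name=spec.name)
            return out
        return pd.to_numeric(col, errors="coerce")


def load_cohort(
    path_or_df,
    *,
    sample_id: str,
    response: str | None = None,
    responder_level=None,
    surv_time: str | None = None,
    surv_event: str | None = None,
    markers: list | None = None,
    covariates: list | None = None,
    sep: str | None = None,
) -> Cohort:
    """Read a delimited patient table and return a validated :class:`Cohort`.

    ``responder_level`` declares which observed response level is coded 1.
    Rows whose response value is neither observed level are flagged in the
    load report, never silently dropped.  Missing values may be empty strings
    or "NA".
    """
    if isinstance(path_or_df, pd.DataFrame):
        raw = path_or_df.copy()
    else:
        path = str(path_or_df)
        if sep is None:
            sep = "\t" if path.endswith((".tsv", ".txt")) else ","
        raw = pd.read_csv(path, sep=sep, na_values=list(MISSING_TOKENS), keep_default_na=True)

    needed = [sample_id] + [c for c in (response, surv_time, surv_event) if c]
    needed += list(markers or []) + list(covariates or [])
    for col in needed:
        if col not in raw.columns:
            raise CohortError(f"mapped column {col!r} missing from input table")

    df = raw.set_index(raw[sample_id].astype(str))
    df.index.name = "sample_id"

    out = pd.DataFrame(index=df.index)
    flagged_rows: list = []
    has_resp = response is not None
    if has_resp:
        col = df[response]
        levels = sorted(map(str, col.dropna().astype(str).unique()))
        if len(levels) != 2:
            raise CohortError(
                f"response column {response!r} has {len(levels)} observed levels "
                f"{levels}; ordinal/multi-level response unsupported"
            )
        if responder_level is None:
            # numeric 0/1 coding is unambiguous; anything else must be declared
            if set(levels) <= {"0", "1", "0.0", "1.0"}:
                responder_level = [l for l in levels if float(l) == 1][0]
            else:
                raise CohortError(
                    f"response levels {levels}: declare responder_level explicitly"
                )
        if str(responder_level) not in levels:
            raise CohortError(
                f"responder_level {responder_level!r} not among observed levels {levels}"
            )
        coded = pd.Series(np.nan, index=df.index)
        notna = col.notna()
        coded[notna] = (col[notna].astype(str) == str(responder_level)).astype(float)
        out["response"] = coded

    has_surv = surv_time is not None and surv_event is not None
    if (surv_time is None) != (surv_event is None):
        raise CohortError("surv_time and surv_event must be mapped together")
    if has_surv:
        t = pd.to_numeric(df[surv_time], errors="coerce")
        unparsed = df.index[df[surv_time].notna() & t.isna()]
        flagged_rows += [(str(i), surv_time) for i in unparsed]
        e = pd.to_numeric(df[surv_event], errors="coerce")
        out["surv_time"] = t
        out["surv_event"] = e

    markers = list(markers or [])
    covariates = list(covariates or [])
    for col in markers + covariates:
        out[col] = df[col]

    report = {
        "n_rows": len(out),
        "missing_per_column": {c: int(out[c].isna().sum()) for c in out.columns},
        "flagged_unparseable": flagged_rows,
    }
    return Cohort(out, markers, covariates,
                  has_response=has_resp, has_survival=has_surv, load_report=report)


def dichotomize(values, spec: MarkerSpec) -> DichotomizeResult:
    """Split a marker into high/low levels, returning the realized cutpoint.

    For continuous markers with ``cutoff="median"`` the cutpoint is the
    population median of non-missing values and a sample is "high" iff its
    value exceeds the cutpoint (strictly by default; ``spec.strict=False``
    switches to >=).  Missing values stay missing.
    """
    values = pd.Series(values)
    if spec.kind == "binary":
        observed = set(values.dropna().unique())
        pos = spec.positive_level if spec.positive_level is not None else 1
        if pos not in observed:
            raise CohortError(f"positive_level {pos!r} unseen in binary marker {spec.name!r}")
        lev = pd.Series(np.where(values.isna(), None,
                                 np.where(values == pos, spec.label_high, spec.label_low)),
                        index=values.index, dtype=object)
        return DichotomizeResult(lev, None)

    vals = pd.to_numeric(values, errors="coerce")
    nonmiss = vals.dropna()
    if nonmiss.nunique() < 2:
        raise CohortError(f"constant marker {spec.name!r}: no stratification possible")
    cut = float(nonmiss.median()) if spec.cutoff == "median" else float(spec.cutoff)
    if spec.strict:
        high = vals > cut
    else:
        high = vals >= cut
    lev = pd.Series(np.where(vals.isna(), None,
                             np.where(high, spec.label_high, spec.label_low)),
                    index=vals.index, dtype=object)
    return DichotomizeResult(lev, cut)


def assign_quadrants(m1_levels, m2_levels,
                     high="high", low="low") -> QuadrantAssignment:
    """Map joint (M1, M2) high/low levels onto quadrants R1-R4.

    Samples missing either level are excluded from all four quadrants and
    counted in ``n_excluded_missing``.
    """
    m1 = pd.Series(m1_levels)
    m2 = pd.Series(m2_levels)
    if len(m1) != len(m2):
        raise CohortError("level vectors differ in length")
    quad = pd.Series(np.nan, index=m1.index, dtype=object)
    complete = m1.isin([high, low]) & m2.isin([high, low])
    quad[complete & (m1 == high) & (m2 == high)] = "R1"
    quad[complete & (m1 == low) & (m2 == high)] = "R2"
    quad[complete & (m1 == low) & (m2 == low)] = "R3"
    quad[complete & (m1 == high) & (m2 == low)] = "R4"
    counts = {q: int((quad == q).sum()) for q in QUADRANTS}
    return QuadrantAssignment(quad, counts, n_excluded_missing=int((~complete).sum()))
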