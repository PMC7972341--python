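# Methods

## The dual-marker evaluation framework

For one marker pair (M1, M2) and one outcome, four nested regression models
are fitted on the identical complete-case set: `outcome ~ M1`, `~ M2`,
`~ M1 + M2` and `~ M1 + M2 + M1:M2`, each optionally plus covariates
(always additive; covariate-by-marker interactions are out of scope).
Continuous markers enter the models raw and unscaled; binary markers are
coded 0/1 via a declared positive level; the interaction regressor is the
elementwise product of the two coded columns.  The five nested comparisons
(each dual model vs each single model, and interaction vs additive) use the
likelihood-ratio test: stat = 2(ℓ_full − ℓ_reduced), clipped at 0, referred
to χ² with df equal to the parameter-count difference.  A mismatch in
complete-case counts between the two fits is a hard error rather than a
silent re-fit, because it would bias the comparison.

**Logistic family.** Newton/IRLS maximum likelihood with intercept
(statsmodels), relative tolerance 1e-9, max 25 iterations.
Quasi-separation is detected from non-convergence or any |coefficient|
above 15 (a logistic log-odds beyond ±15 is numerically degenerate); such
fits are flagged and the pair is skipped with a recorded reason rather than
penalized — penalization would change the LRT's calibration.  Per-model
performance is ROC/AUC computed on the fitted response probabilities (not
raw marker values), so single-marker curves of unfavorable markers still
display AUC ≥ 0.5 and all four curves are comparable in one plot.  The AUC
is the Mann–Whitney statistic with ties counting ½; its variance comes from
DeLong's structural components (placement values), with a normal-theory 95%
interval truncated to [0, 1].

**Cox family.** Partial-likelihood maximization with the Efron correction
for tied event times (lifelines); the same flag-and-skip policy covers
monotone likelihood (a regressor that perfectly orders the events).
Zero-variance regressors are held at coefficient 0; if every regressor is
degenerate the null partial log-likelihood is computed directly
(ℓ₀ = −Σ_j Σ_{l<d_j} log(n_j − l), identical for Efron and Breslow).
Performance is the Gönen–Heller concordance probability estimate, computed
from the fitted linear predictors only:
K = (2/n(n−1)) Σ_{i<j} 1/(1 + e^{−|η_i − η_j|}).  It equals 0.5 exactly
when all predictors tie and never uses the observed event ordering; the
smoothed variant and its variance estimator are not implemented (only point
values are reported downstream).  Guards before fitting the family:
≥ 20 complete cases (≥ 5 per response class for the logistic family,
≥ 10 events for the Cox family) and |Pearson r| ≤ 0.999 between the marker
regressors; all configurable.

## Dichotomization and quadrants

Continuous markers are split at the population median of the non-missing
values by default (or a user-supplied cutpoint).  A sample is "high" iff
its value is strictly greater than the cutpoint; with heavy ties this makes
the median sample itself deterministically "low".  The inequality is
configurable to ≥ since conventions differ between tools.  Joint levels map
to quadrants R1 = (M1 high, M2 high), R2 = (low, high), R3 = (low, low),
R4 = (high, low); samples missing either level are excluded from all four
and counted separately, so quadrant counts always partition the complete
cases.  Missing data are handled by complete-case (pairwise) deletion per
analysis, never imputation — an exploratory tool should not add unstated
modeling.  Ordinal variables with more than two levels are rejected at
load time.

## Univariate statistics

* Wilcoxon rank-sum: exact enumeration when both groups have ≤ 25
  observations and the pooled sample has no ties, otherwise the normal
  approximation with tie and continuity corrections.
* Spearman correlation: average ranks for ties; two-sided p from the
  t approximation t = ρ√((n−2)/(1−ρ²)), chosen over exact permutation for
  determinism at every n.
* Fisher's exact 2×2 test: two-sided hypergeometric rule (sum of table
  probabilities ≤ the observed one).  The reported effect size is the
  sample odds ratio with a Haldane–Anscombe +0.5 applied only when a cell
  is zero — not the conditional-MLE odds ratio; a zero margin returns
  p = 1 with a degenerate flag.
* Response-rate intervals: Clopper–Pearson exact by default (matching the
  conservative exact-testing convention), Wilson available.
* Bonferroni min(1, m·p) and Benjamini–Hochberg step-up adjustments.

## Survival descriptives

Kaplan–Meier curves use the product-limit estimator with Greenwood
variance.  Pointwise 95% bands are built on the log-survival scale,
S·exp(±z√var(log S)), clipped to [0, 1].  The median is the smallest time
with S ≤ 0.5; its confidence bounds are the crossing times of the lower and
upper bands with 0.5, either side reported as missing when the band never
crosses (common in small or heavily censored strata).  Log-rank tests use
the k-group hypergeometric-variance statistic with df = k − 1.  Conditional
KM analysis runs four stratified 2-group log-rank tests (M2 within each M1
level, M1 within each M2 level) and Bonferroni-adjusts all four as one
family (m = 4); a non-evaluable stratum keeps the family size at 4.

## Partner search

For each candidate the four-model family is fitted and
p_dual_vs_M1 = min(p additive-vs-M1, p interaction-vs-M1) — the stated
min-p rule taken literally (no AIC pre-selection), and analogously versus
M2.  The min over two tests mildly inflates the null rejection rate (the
suite measures roughly 5–12% at nominal 5%), which is accepted and
documented: the rule is an exploratory prioritization, not a calibrated
test.  BH adjustment is applied separately to the dual-vs-M1 and dual-vs-M2
columns across evaluated candidates (the adjusted family is configurable in
principle; column-wise was chosen as the natural screening unit).  The
signed score is −log10(p_dual_vs_M1) with sign +1 when the candidate's
single-marker effect is favorable — positive logistic coefficient, or
*negative* Cox log-hazard coefficient (longer survival); p = 0 underflow is
capped at 300.  Degenerate candidates (constant, |r| > 0.999 with M1,
separation/monotone-likelihood flags, insufficient n or events) become
skipped rows with reasons, never silent omissions.  Rows are sorted by
p_dual_vs_M1 with a stable name tie-break, making outputs byte-reproducible.

## Synthetic cohorts

The generator emulates a mid-sized immunotherapy-trial biomarker table.
Defaults: n = 300 patients; markers standard normal; binary response from
logit P = b0 + b1·m1 + b2·m2 + b12·m1·m2 with b0 = −1 (≈ 27% responders),
b1 = 0.8 (favorable), b2 = −0.6 (unfavorable), b12 = 0; survival from an
exponential proportional-hazards model with baseline 0.08 events/month
(median ≈ 8.7 months), log-hazard effects g1 = −0.5, g2 = 0.3, g12 = 0;
independent exponential censoring at 0.03/month plus an administrative
cutoff at 24 months (roughly a third censored).  Decoy markers are mutually
independent standard normals.  The exponential baseline (rather than
Weibull) was chosen for its closed-form oracles — e.g. the marginal event
probability λ/(λ+λc) under exponential censoring, which the tests check.
What the generator does **not** emulate: correlated co-expressed gene
panels, non-linear marker effects, informative censoring, measurement
error.  Passing tests therefore demonstrate correctness of the statistical
machinery under the generating model, not robustness to those real-data
features.

## Problem sizes used by the checks

Type-I-error calibration uses 1000 replicates at n = 200 (the test suite;
the acceptance script uses 1000 logistic / 500 Cox replicates).
Coefficient recovery fits the saturated model on 200 (suite) or 100
(script) cohorts of n = 2000.  Search ranking uses 100 (suite) or 50
(script) panels of 50 decoys plus one true additive partner at n = 400;
interaction detection uses a log-HR 2.5 interaction at n = 500.  These
sizes give Monte-Carlo standard errors well inside the asserted bands while
keeping a full run to a few minutes on one CPU.

## Known limitations

Linear effects only (no splines); no covariate×marker interactions; no
multi-level ordinal variables; no >2-marker combinations; no Firth
penalization for separated logistic fits; no cross-validated performance
metrics; no time-varying covariates, competing risks or proportional-
hazards diagnostics; search runs serially (large expression panels will be
slow).
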