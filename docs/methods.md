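# Methods

## Estimand and data format

For each outcome (death, MOF, ARDS, VTE, transfusion, threshold-derived
coagulopathy) the pipeline estimates the discrete-time hazard: the
probability that a patient who is alive, uncensored and event-free at the
start of interval (t_{j-1}, t_j] has the event inside it, as a function of
everything measured up to t_{j-1}. The cohort is restructured into
person-period rows to make this an ordinary binary prediction problem.
Conventions:

* intervals are half-open (t_{j-1}, t_j]; an event stamped exactly at a
  cutoff belongs to the interval ending there;
* death is terminal: it removes the patient from every outcome's risk set
  and blanks all later measurements;
* non-terminal outcomes are first-event processes — a patient leaves that
  outcome's risk set at the first observed event but stays in the others';
* a (patient, interval) whose outcome label is missing contributes no row
  for that interval and the patient stays at risk afterwards; outcomes are
  dropped, never imputed;
* "overall" mode is the companion one-row-per-patient problem: admission
  predictors only, y = outcome ever during follow-up.

An outcome × interval cell is modelled only when it has at least
`min_events` events among at-risk rows (default 50, matching the
50-per-level variability floor for predictors; both are configurable
because the floor is a power heuristic, not a law).

## Missingness

Incompletely observed predictors are encoded, not imputed: X becomes
Δ = 1{observed} and Δ·X (observed value, else 0). This keeps every
learner's design complete while letting the fact of non-measurement carry
signal — in critical care, which labs get drawn is itself informative.
Δ columns are created only for variables with observed missingness (a
constant Δ = 1 column is uninformative), compete in variable-importance
rankings on equal terms, and are labelled in reports.

For threshold-derived labels (e.g. coagulopathy = INR > 1.4 or PTT ≥ 35) a
row with any missing source gets a missing label, even if an observed
source already qualifies; we prefer the simple, auditable rule over
three-valued logic since label missingness is handled downstream anyway.

## The super learner

Candidates (defaults; all configurable per run):

| family | implementation | notes |
|---|---|---|
| logistic | near-unregularized logistic regression (C = 10⁴, standardized) | |
| linear-probability | OLS, predictions clipped to [0, 1] | |
| gam (df 2, 4, 6) | logistic regression on per-feature cubic B-spline bases | df sets the knot count; low-cardinality columns enter linearly |
| random forest | 200 trees, unlimited depth | seeded per learner name |
| lasso | L1 logistic path, C chosen by internal 3-fold AUC CV | |
| polynomial sieve | logistic on polynomial expansion, degree ∈ {1,2,3} by internal CV | degrees whose expansion exceeds 2,000 columns are skipped |

Stacking: a stratified V-fold plan (default V = 10; stratification keeps
per-fold event counts within one of proportional, which rare events
require) produces the out-of-fold matrix Z; weights solve
min_{α≥0} ‖y − Zα‖² by NNLS and are rescaled onto the simplex. Rescaling
preserves which weights are exactly zero; an all-zero or degenerate
solution falls back to uniform weights with a warning. Learners whose fit
raises on any fold are dropped and logged rather than aborting — real
cohorts make some fits singular — and the run continues while at least one
candidate survives. Per-learner seeds derive from the learner *name*, so
permuting the library changes nothing.

## Honest performance

The entire super learner (inner CV included) is refit inside each outer
fold; held-out predictions are pooled and summarized by the Mann–Whitney
AUC (ties one half). The pooled rather than fold-averaged estimate is used
because per-fold AUCs are unstable with few events; fold AUCs are still
reported.

The confidence interval uses variance
`se² = se_HM² + Var(fold AUCs)/V`, where se_HM is the Hanley–McNeil
asymptotic SE of the pooled statistic. The second term is deliberate:
cross-validated predictions are not fixed scores — each outer fold is
scored by a different refit, and evaluation rows also train the other
folds' models. In null simulations (outcome independent of predictors,
n = 2000) the pure Mann–Whitney interval covered 0.5 in only ~82% of
replicates, as did DeLong-style and fold-averaged variants; adding the
between-fold component restored ~92% coverage. The component is an
approximation, not an exact correction (no unbiased estimator of CV
variance exists), and intervals in high-signal settings are essentially
unchanged by it.

Cells with CV-AUC > 0.85 are flagged high-performance; variable importance
is reported only for those, since an importance ordering from a barely
discriminating model is noise.

## Variable importance

The forest for importance is refit on the full supported cell (not reused
from ensemble folds) so it sees all rows. The default score is total Gini
impurity decrease normalized to sum 1 — cheap and stable; permutation
importance (mean increase in misclassification or 1 − AUC over seeded
permutations of one column) is available behind a flag. Ties in the top-k
ranking break lexicographically by variable name so reports are
deterministic.

## Synthetic cohort generator

The generator is the test bed, not a physiologic model. Structure: a
scalar latent severity S ~ N(0,1) per patient; time-varying signals
X_t = load·S + e_t with e_t Gaussian AR(1); per-interval logistic hazards
on baseline covariates, the interval-start values of time-varying signals,
and optionally S itself; censoring by death with events stamped at
interval midpoints; cell-wise missingness with
P(miss) = expit(logit(base) + c·S), where c > 0 makes sicker patients'
labs go missing (MNAR). Three independent random streams (covariates,
events, missingness) spawn from one seed, so switching missingness off
never changes which patients have events.

Default conditions (`default_config`) emulate a severely injured trauma
cohort at n = 1500: cumulative mortality ≈ 18%, MOF ≈ 10%, ARDS ≈ 10%,
transfusion ≈ 20% concentrated early, VTE a late outcome with enough late
events to be supported only at 96/120 h. Most of the mortality signal
flows through measured physiology (lactate, pressure, coagulation), with
a residual latent term for the part of severity charts never capture;
admission-data death prediction then sits near CV-AUC 0.91 against a
Bayes ceiling (`true_discrimination`, Monte-Carlo) near 0.94. What the
generator does *not* emulate: realistic marginal distributions or units,
organ-system coupling, treatment feedback, discharge, or measurement-grid
irregularity. Passing tests therefore demonstrate that the machinery
recovers known structure under these mechanisms, not that any clinical
cohort would yield particular AUCs.

The inter-measurement correlation (AR persistence 0.7–0.85) and the MNAR
strength (severity coefficients 0.5–0.8 on the default labs) are free
parameters of the emulation, chosen once as plausible for ICU physiology
and labs, not estimates of any cohort.

## Problem sizes used by the test suite

Simulation-backed checks run at sizes chosen to keep the default suite
fast while leaving the assertions' proportional thresholds intact: the
ensemble-vs-best-candidate comparison uses 10 cohorts of n = 600 (margin
0.02, ≥ 9/10); null calibration uses 100 cohorts of n = 2000 (coverage
≥ 90/100); oracle recovery uses one n = 3000 cohort against a 40,000-draw
Monte-Carlo ceiling (±0.03); MNAR importance recovery uses 20 cohorts of
n = 800 with 30 noise covariates (Δ in top-10 Gini in ≥ 16/20);
person-period invariants run over 100 random n = 200 cohorts.

## Known limitations

* The CI's between-fold variance term is a pragmatic correction; a full
  influence-function treatment of nested CV-AUC is future work.
* The variability filter checks continuous variables only for ≥ 50
  non-missing, non-constant values — the closest analogue of the
  per-level rule; raw variables are filtered first, dummies re-checked.
* The "coagulopathic trajectory" label (trend in INR/PTT across adjacent
  grid times) is exposed via threshold configuration but has no canonical
  definition; treat results for it as experimental.
* Stata ingestion relies on pandas' DTA reader; extended missing codes
  map to the single NaN sentinel, value labels are not interpreted.
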