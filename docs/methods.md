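# Methods

## The estimation problem

Two antidepressant alternatives are compared on a rare binary outcome
(hospital admission for self-harm or death by suicide within three months of
the first prescription). The estimand throughout is a **risk difference per
100 patients**, estimated by least squares rather than logistic regression so
that effects are collapsible and directly comparable across estimators.
Confounding by indication is the central threat: prescribers choose drugs
partly on characteristics (severity, comorbidity, age) that also predict the
outcome, and several of those are unrecorded.

The identification strategy is a preference-based instrumental variable.
Each physician's latent preference shifts the drug their patients receive;
prescriptions the physician issued to *earlier* patients proxy that
preference and serve as surrogate instruments. Identification requires the
usual three IV assumptions (instrument–exposure association, no direct
instrument–outcome path, no instrument–confounder association), plus either
monotonicity of preference effects or no effect modification by the
instrument; the package's diagnostics probe the testable parts (first-stage
strength; covariate balance; physician fixed effects against a direct
physician effect on the outcome) and the Durbin–Wu–Hausman test compares the
conventional and instrumented answers.

## Synthetic data-generating process

The generator (`prefiv.simulate`) emulates the situation the method was
designed for, with every latent quantity returned for recovery testing.

- **Preference.** Physician preference is a random intercept on the log-odds
  scale, `alpha ~ N(0, preference_sd²)`, optionally with a linear calendar
  drift (default 0 — nothing in routine data pins down a preference process,
  so the simplest process that makes depth-k instruments informative is
  used).
- **Drug choice.** `logit P(X=1) = intercept_rx + alpha + Σ beta_c C_c +
  gamma_rx·U + trend_rx·t`, with `U ~ Bernoulli(0.5)` the unmeasured
  confounder and `t` years since the calendar start. A binary `U` keeps
  omitted-variable-bias arithmetic tractable.
- **Covariates.** Twelve binary baseline indicators (BMI>25, hospitalization
  in the prior year, >13 consultations, age>40, >5 prescriptions, male, ever
  smoked, prior depression diagnosis, prior self-harm, prior hypnotic, prior
  antipsychotic, Charlson>0) with prevalences matching a UK primary-care
  antidepressant cohort. A physician-level random shift (`casemix_sd`) on
  each covariate's log-odds induces the small instrument–covariate
  associations seen in real data: instruments inherit case-mix clustering,
  so instrument imbalance is nonzero but much smaller than exposure
  imbalance.
- **Outcome.** A clipped linear risk model,
  `P(Y=1) = clip(baseline_risk + tau·X/100 + gamma_y·U/100, 0, 1)`, so the
  risk-difference estimand equals the configured `tau` exactly. The
  generator refuses configurations where clipping touches more than 1% of
  rows. Events are placed uniformly inside the outcome window.
- **Timing and structure.** Patient arrival dates are uniform over the
  calendar window (1995–2010 by default) and ordered within physician, ties
  broken by patient id, giving the total order instrument construction
  needs. Each physician also issues a configurable number of warm-up
  prescriptions (default 10) before the calendar window so the ≥10-prior
  exclusion rule and depth-7 instruments have support from the first cohort
  patient. Physicians are grouped into practices; a configurable fraction
  (default 50%) of practices is flagged as linked to outcome data.
- **Defaults.** 500 physicians × 100 patients (roughly the per-physician
  volume of the motivating setting at desk scale); `preference_sd = 1`
  (first-stage risk difference in the low teens per 100);
  `intercept_rx = −0.8`, which with the default covariate effects gives a
  comparator share near 55%; `baseline_risk = 0.0015` (0.15 events per 100).

What the generator does **not** emulate: dosing titration and repeat
prescriptions, realistic market-share dynamics across drugs, clinical coding
(Read/ICD), multi-practice patients, and outcome misclassification. Passing
tests therefore demonstrate the statistical machinery under the stated
model, not robustness to those real-data features.

## Cohort construction choices

- "Within 12 months of joining the practice" is implemented as 365 days, "3
  months" as 91 days; both configurable.
- The outcome window is left-open, right-closed: events on the index date
  itself are excluded because they may be the indication rather than a
  consequence; an event exactly at day 91 counts.
- Same-date index ties break by (drug class, drug name, record id).
- Age at index is `index_year − birth_year` (year-only birth data).
- "Fewer than 10 prior prescriptions" counts the physician's prior
  first-time (index) prescriptions within the dataset; a switch
  (`prior_count_mode="all"`) counts all prescription events instead, since
  the source phrasing is ambiguous.
- BMI outside [15, 100] is set missing (boundary values retained); the BMI>25
  indicator is recomputed from in-range values only.
- Exclusion rules run in a fixed documented order, a row is counted under
  the first rule that catches it, and permuting the order changes per-rule
  counts but never final membership (tested).

## Instrument construction choices

- A physician's history is the ordered sequence of first prescriptions of
  distinct patients; "previous k prescriptions" are the last k history
  entries dated **strictly before** the row's index date. This enforces the
  temporal-validity invariant (nothing dated on or after the index date can
  leak into an instrument); the patient-id tie rule only orders same-date
  *earlier* entries among themselves. The current patient's own records
  never contribute.
- Instrument coding always matches exposure coding (Z = 1 denotes the same
  drug as X = 1), so first-stage risk differences are positive under
  preference persistence.
- Rows whose physician lacks k priors are dropped and counted; retained rows
  nest across depths (depth 7 ⊆ depth 3 ⊆ depth 1).

## Estimation and inference choices

- Cluster-robust variance uses the sandwich with small-sample factor
  `G/(G−1)·(N−1)/(N−k)` (the convention of the major commercial
  implementations this methodology is usually run in); CIs and p-values use
  a t/F reference with `G−1` degrees of freedom. With singleton clusters the
  OLS SE reduces exactly to HC1.
- 2SLS is plain two-stage least squares (no LIML/GMM). Its clustered
  variance is built from **structural** residuals `y − Xβ̂`, never the
  second-stage plug-in residuals. In the just-identified case the
  coefficient solves `Z'Xβ = Z'y` directly, which matches the hand-computed
  Wald ratio to machine precision.
- A partial F below 10 triggers a weak-instrument warning, not a failure.
- The DWH test is the control-function form: append the first-stage residual
  to the outcome regression and test its coefficient with a cluster-robust
  Wald test. The classical variance-difference form can be negative definite
  under clustering; the control-function form cannot.
- The LM test for added instruments is `N·R²` from regressing the base
  first-stage residuals on the added instruments plus controls, referred to
  χ² with one degree of freedom per added instrument.
- The fixed-effects IV demeans all variables within physician before 2SLS
  (clusters = physicians; the absorbed effects are counted in the
  degrees-of-freedom correction). It identifies the effect only from
  physicians whose instrument varies, and probes a direct physician effect
  on the outcome (an exclusion-restriction violation for plain 2SLS).
- Propensity-score matching is ATT: logistic score on all covariates except
  BMI (missingness), each exposed matched to the nearest control within a
  0.01 caliper, sampling controls with replacement, matching in descending
  score order with equidistant ties going to the smaller control id, and a
  frequency-weighted variance for re-used controls. With coarse (few-pattern)
  covariate sets the deterministic tie rule re-uses few controls and the
  estimate is noisy; that is visible in its reported `n_clusters`.
- Year adjustment always uses per-year indicator variables, not a linear
  term — prescribing trends are markedly nonlinear.
- The prevalence difference ratio is reported as unstable (not a number)
  when the exposure risk difference is below 0.1 per 100, where the ratio
  explodes; whether its inputs are crude or year-adjusted is a flag
  (year-adjusted by default).
- The Mahalanobis imbalance distance uses the pooled within-group covariance
  of the covariates, ×100 for display; only the between-group distance and
  its percent reduction are treated as reproducible arithmetic.

## Validation studies and problem sizes

The replicate studies (`prefiv.experiments`) choose desk-scale sizes that
keep the asymptotics honest: recovery runs 200 replicates of 500 physicians
× 100 patients with `tau = −10`, confounder effects +1.5 (log-odds, on
prescription) and +50 per 100 (on outcome) and `baseline_risk = 0.2` so the
linear risk model never clips; DWH size uses 500 replicates of 100 × 30; the
LM noise study 500 replicates of 50 × 40; the oracle check 1,000 datasets of
n ≤ 50 with a non-degenerate first stage enforced. The analysis scripts run
scaled-down versions of the same studies; `scripts/acceptance.py` runs them
at full size.

## Known limitations

- The outcome model is linear in probability; with rare outcomes predicted
  risks can sit near 0, and least-squares inference leans on the clustered
  CLT rather than likelihood calibration.
- The DWH rejection rate is mildly anticonservative at ~100 clusters
  (observed ≈ 5–7% at a nominal 5%), consistent with known small-G behavior
  of cluster-robust tests.
- Monotonicity / no-effect-modification — the assumptions that fix *which*
  patients' effect is identified — are untestable and are not simulated as
  violations.
- No time-decay weighting of prescription histories and no practice-level
  instruments are implemented.
- The package ships no command-line entry point: the library functions and
  the `analysis/` scripts are the interface.
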