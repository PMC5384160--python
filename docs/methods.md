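# Methods

`tdroc` estimates time-dependent ROC curves and AUCs for a scalar marker
(or risk score) under right censoring, and for longitudinally measured
markers. This note records the statistical models implemented, the
defaults and numerical choices that matter, what the synthetic generators
emulate, and the limitations of both.

## Data model and definitions

A baseline cohort is a set of triplets (Z_i, δ_i, X_i): observed time
Z_i = min(T_i, C_i) for latent event time T_i and censoring time C_i,
event indicator δ_i, and marker X_i measured at baseline (higher values
taken as more indicative of the event). All times are carried in one
user-declared unit (days by default); nothing inside the library converts
units. A longitudinal cohort adds per-subject visit times s_ik with marker
values Y_ik; the lag T_i − s_ik ("time before event") is derived where
needed, never stored.

Three case/control conventions are implemented:

* **Cumulative/dynamic (C/D)** — at horizon t, cases are subjects with
  events in (0, t], controls are subjects event-free beyond t.
* **Incident/dynamic (I/D)** — cases have their event exactly at t (the
  riskset splits into incident cases and dynamic controls); the natural
  companion of hazard models, and the basis of the concordance summary.
* **Incident/static (I/S)** — incident cases at t, controls event-free
  past a fixed horizon t* regardless of t ("long-term survivors").

Every curve estimator evaluates sensitivity and one-minus-specificity on
the grid of unique marker values with ±∞ sentinels, so the limiting points
(0,0) and (1,1) are always on the curve and no binning is introduced. The
scalar AUC is the trapezoidal integral of that step curve, which equals
the matching pairwise (Mann–Whitney-type) statistic with tied markers
counted 1/2 — verified against explicit double sums in the tests.

## Cumulative/dynamic estimators

* **naive** — observed proportions after dropping subjects censored before
  t. Consistent only when censoring is absent before the horizon; kept as
  the reduction target every other estimator must reproduce on uncensored
  data.
* **cd1** — conditional Kaplan–Meier (Bayes) plug-in,
  Se(c,t) = {1 − Ŝ(t|X>c)}(1 − F̂_X(c)) / (1 − Ŝ(t)). The quadrant
  probability plug-in is not a valid bivariate distribution under
  censoring, so the curve can be non-monotone and leave [0,1]; raw values
  are returned and flagged (`out_of_bounds`), never clipped.
* **cd2** — Akritas nearest-neighbour bivariate survival estimator. The
  conditional survival Ŝ_λ(t|X_i) is a product-limit over the 0/1
  neighbourhood |F̂_X(X_i) − F̂_X(x)| < λ_n on the empirical-CDF scale, so
  the estimator is invariant to strictly increasing marker transforms;
  sensitivity and specificity are monotone and bounded by construction.
  Default half-width λ_n = 0.25 n^(−1/3) (the customary O(n^(−1/3)) rate
  with the constant used by the analogous conditional-KM plug-in
  guidance), overridable.
* **cd3** — Kaplan–Meier-like estimator distributing KM probability
  increments Ŝ(t_{k−1}) − Ŝ(t_k) over the markers of the subjects failing
  at each event time (closed form rather than the original recursion).
  Tied event times share the increment equally among the tied cases. Its
  sensitivity is algebraically identical to the IPCW sensitivity of cd5
  (asserted to 1e−12 in tests); its specificity can be non-monotone.
* **cd4** — proportional-hazards plug-in: S(t|X_i) from a Cox fit, with
  expectations replaced by sample means. Monotone and bounded, but not
  invariant to marker transforms (the Cox score changes); the tests
  document that asymmetry explicitly.
* **cd5** — inverse-probability-of-censoring weighting: event records get
  weight δ_i / Ŝ_c(Z_i−), with Ŝ_c the Kaplan–Meier curve of the
  censoring distribution evaluated at the left limit (avoiding a
  subject's own censoring mass); specificity is empirical.
* **cd6** — conditional IPCW: the weights condition on the marker,
  Ŝ_c(·|X_i), by default from the nearest-neighbour weighted KM applied
  to censoring times (a proportional-hazards censoring model is available
  by flag). This is the family member robust to marker-dependent
  censoring, and the robustness study below operationalises that claim.
* **cd7** — interval-weighted AUC over (τ1, τ2]: a weighted average of a
  base C/D AUC at the distinct event times, weights proportional to the
  KM drop at each time. Increments are taken in absolute value so the
  weights are a distribution summing to one exactly (the raw increments
  are negative as printed in the defining display).
* **cd8** (conditional-absolute-risk plug-in family) — AUC computed from
  model risks F̂(t; X_i) via the mean-normalised pairwise form
  Σ_{i≠j} w_ij F_i (1−F_j) / Σ_{i≠j} F_i (1−F_j), w_ij the half-weight
  order indicator. The denominator excludes i = j: that is what makes a
  constant risk give AUC = 1/2 exactly (exchangeability), and the rank
  form is verified against the explicit double sum at 1e−10. Risk models:
  Cox with hand-computed Breslow baseline at marker 0 (`vl_cox`), Aalen
  additive cumulative coefficients (`vl_aalen`), and the nearest-neighbour
  conditional KM with half-width 0.25 n^(−1/5) (`vl_km`). The
  nearest-neighbour risk is a proper product-limit complement
  1 − Π(1 − dN_w/Y_w).

## Incident/dynamic estimators and concordance

* **id1** — three-step Cox procedure: fit γ by partial likelihood
  (lifelines, Breslow ties), smooth the scaled Schoenfeld residuals to get
  a time-varying coefficient γ̂(t), then take sensitivity as the
  exponentially tilted riskset survivor function of the marker with
  weights π_i ∝ exp(X_i γ̂(t)), and specificity empirical over dynamic
  controls. γ̂(t) = 0 reduces the sensitivity to the riskset's empirical
  survivor function; γ̂(t) → ∞ concentrates it on the riskset maximum —
  both limits are tested.
* **Concordance C^τ** — weighted average of the incident/dynamic AUC over
  event times in (0, τ] with weight 2 f(t) S(t) / (1 − S(τ)²). The
  discrete weight at t_k is taken as (S(t_{k−1})² − S(t_k)²)/(1 − S(τ)²),
  i.e. 2 f̂ S̄ with the midpoint survival — the telescoping form, so the
  weights sum to one exactly rather than to 1 ± O(f̂²).
* **id2** — weighted mean rank: the per-riskset concordance U-statistic
  A(t) (exact pair enumeration, strict inequality) averaged over a
  bandwidth-h neighbourhood of event times, uniformly or with normalised
  Gaussian kernel weights. Default bandwidth spans the nearest 10% of
  event times; an IMSE-optimal choice is a documented research option,
  not a default, because no concrete selection recipe accompanies the
  estimator. h → 0 at an event time reduces to A(t) exactly.
* **id3** — fractional-polynomial model
  link(AUC(t)) = β₀ + Σ_g β_g t^(p_g), powers from
  {−2, −1, −½, 0, ½, 1, 2} (t^(0) meaning ln t), fitted by maximising the
  pseudo partial-likelihood Π_k AUC(t_k)^{n1_k}(1−AUC(t_k))^{n2_k} where
  n1/n2 are concordant/discordant pair counts per riskset. The power set
  is searched exhaustively at fixed degree (repeated powers excluded at
  G ≤ 2); β is optimised by BFGS within each power set. The time axis is
  rescaled by the median event time before powers are applied — t² on
  day-scale data otherwise overflows the link scale; estimates are
  reported on the original axis. Complete separation pins the AUC to the
  boundary and flags the fit. The integrated AUC uses the analytic fitted
  curve with uniform weight.

## Incident/static and longitudinal methods

* **is2** — the id1 construction with a redefined riskset: incident cases
  at t plus static controls event-free beyond t*. Specificity is
  empirical over the static controls. The marker is either the baseline
  value or the last value before a landmark (`last_value_cohort`): keep
  subjects strictly at risk past the landmark with at least one visit at
  or before it, use the latest such visit's value, leave the time axis on
  the original scale. Landmark membership uses strict Z > s0, matching
  the strict inequalities in the control definitions.
* **ecd2** — cd2 applied to the last-value cohort at a landmark; inherits
  cd2's monotonicity, boundedness and transform invariance, and reduces
  exactly to cd2 on single-baseline-visit data.
* **ad1** — induced binormal ROC from case/control linear mixed models.
  Case trajectories: Y = b_{0i} + b_{1i}s + β₀ + β₁s + β₂·TBE + β₃·s·TBE + ε
  with TBE the time before event; controls omit the TBE terms. Random
  intercept and visit-time slope per subject, fitted by REML
  (statsmodels MixedLM). Visit time and TBE are internally rescaled to
  order one before optimisation — day-scale random-slope variances
  (~1e−7) sit seven orders below the intercept variance and stall the
  optimiser — and all estimates are mapped back to input units. The
  model-implied mean uses the full fixed-effect design ([1, s, t, st] for
  cases); the SD uses only the random-effect columns [1, s] plus residual
  variance, since those are the only stochastic terms. The ROC is the
  Gaussian location-scale curve written in the standard CDF convention
  ROC(p) = Φ(a₀ + a₁Φ⁻¹(p)), a₀ = (μ_D − μ_D̄)/s_D, a₁ = s_D̄/s_D,
  AUC = Φ(a₀/√(1+a₁²)), cross-checked against numerical integration at
  1e−6.
* **ad2** — ROC-GLM: all case/control visit pairs, indicator
  I(Y_case ≥ Y_ctrl) regressed with a probit link on Φ⁻¹(placement) and
  the case's time before event. Placement values are control *survivor*
  fractions (the false-positive rate at the control value as threshold),
  pooled with midrank ties — using CDF fractions instead flips the sign
  of the binormal slope. Pair sets above 200k are subsampled
  reproducibly. Point estimates are consistent despite the pair
  dependence; no pair-clustered standard errors are provided.
* Case/control assignment for ad1/ad2: subjects with an observed event
  are cases; censored subjects are retained as controls (these methods do
  not themselves model censoring; the convention is recorded in the fit
  metadata).

## Survival primitives

Kaplan–Meier curves (event and censoring) are a small hand-rolled
product-limit routine — cd1 and the nearest-neighbour machinery fit
thousands of subset curves per call, and the routine is cross-checked
against lifelines' KaplanMeierFitter in the tests. Ties follow the
standard convention (events precede censorings at a tied time); Gill's
identity Ŝ(t)·Ŝ_c(t) = empirical P(Z > t) on tie-free data is asserted at
1e−10. Cox fits use lifelines with the Breslow baseline recomputed by
hand at marker 0 (lifelines' stored baseline is at the covariate mean).
The time-varying coefficient smooths scaled Schoenfeld residuals
(γ̂ + m·V̂·s_k) with lowess; smoothing distances use the event-time *rank*
axis — the customary "rank" time transform for these diagnostics — because
late event times are sparse with noisy residuals and dominate the boundary
window on the raw axis (raw-axis sup-error under proportional hazards was
~0.3–0.4 at n = 1000 versus ≤ 0.22 on the rank axis). Default span: 0.6 of
the events, widened with a warning below five events per window.

Bootstrap inference resamples whole subjects with replacement (whole
trajectories for longitudinal cohorts), B ≥ 50, percentile intervals,
deterministic given the seed; failed resamples are redrawn and more than
10% failures is a hard error. The interval is clipped to bracket the
point estimate. A coverage study in the test suite (95% nominal, B = 200,
100 outer replicates, n = 120) requires ≥ 85% empirical coverage.

## Synthetic cohorts and oracles

The baseline generator draws a standard-Gaussian marker with an
exponential, Weibull or additive hazard effect and censoring that is
absent, independent exponential, or marker-dependent with hazard
rate·exp(ηX) — the structure that separates the censoring-robust
estimators (cd2/cd6/cd8) from the conditional-KM plug-in (cd1). Every
simulated cohort carries an oracle exposing the true conditional risk
F(t|x) and density, the event fraction, and the true C/D and I/D AUCs by
quadrature over the marker law (trapezoid on a 4001-point grid over ±8
SDs with a cumulative inner integral; checked against 10⁶-draw Monte
Carlo). γ = 0 returns 1/2 exactly.

The longitudinal generator follows the case/control mixed models above.
Its default trajectory parameters are the magnitudes of the published
PBC-style score fits (intercepts O(1), day-scale slopes O(1e−4), residual
SDs 0.29/0.22), with five yearly visits jittered ±30 days; case event
times are uniform over the follow-up window and visits at or after the
event are discarded, so the time before event is defined at every
retained visit.

What the generators do **not** emulate: informative visit processes,
competing risks, measurement error in the marker, non-Gaussian marker
laws, and covariates beyond the scalar marker. Passing tests therefore
demonstrate correctness of the estimators under their stated assumptions,
not robustness to those further departures.

A separate test oracle deserves note: drawing each event from the current
riskset with probability proportional to the marker's rank gives an
incident/dynamic AUC of exactly 2/3 at every event time regardless of
riskset size (Σ r(r−1) / ((m−1)Σ r) = 2/3), which pins down the
fractional-polynomial estimator's constant-AUC recovery without any
asymptotic argument.

## Problem sizes and tolerances in the test suite

Deterministic identities are asserted at 1e−10–1e−12; quadrature
cross-checks at 1e−6. Statistical recovery uses n = 2000 for the
cross-estimator agreement (cd4/cd6/vl_cox within 0.03 of each other and
0.05 of the oracle at the median event time), 200+200 subjects for the
mixed-model recovery (within 2 SEs), n = 1000 for the constant-AUC
recovery (within 0.03), and 200 replicates of n = 300 for the
marker-dependent-censoring robustness ordering (mean absolute error of
cd6 below cd1). These sizes were chosen so each study resolves its
question with comfortable margin while the whole suite stays quick.

## Known limitations

* Single scalar marker only: no covariate adjustment in any estimator
  (the multi-covariate weights of the incident family are deliberately
  out of scope, as is the covariate-adjusted nearest-neighbour variant).
* No competing-risks event codes.
* cd1's non-monotone, unbounded behaviour is reported, not repaired.
* id2 provides no asymptotic variance; use the bootstrap.
* The ad1/ad2 treatment of censored subjects as controls is a
  convention, not a correction; with heavy censoring close to events it
  biases the control distribution toward incipient cases.
* The published worked-example case mean (0.373) is not reproducible
  under the stated visit-time/time-before-event convention (only with the
  two arguments interchanged); both arguments are explicit in
  `ad1_moments`, and that value is not used as a reference anywhere.
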