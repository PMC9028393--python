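# Methods

This note documents the models, algorithms, default parameters and design
choices behind `tigepk`, and what the synthetic-data experiments do and do
not demonstrate.

## Structural and statistical model

Plasma kinetics follow a two-compartment mammillary model with zero-order
infusion input and first-order elimination from the central compartment,
parameterized as clearance CL (L/h), central volume Vc (L),
inter-compartmental clearance Q (L/h) and peripheral volume Vp (L).  The
solution is the standard biexponential closed form; the macro rate constants
are computed in the sum/product form (α from the quadratic, β = k10·k21/α)
so that the small root keeps full relative precision when Q ≪ CL — the
one-compartment degenerate limit used by several tests exercises exactly
this regime.  `1 − exp(−x)` terms go through `expm1` to avoid cancellation
for slow rates.  Linearity gives two exact identities used throughout:
multi-dose curves are sums of single-dose curves, and steady-state
AUC over 24 h equals daily dose / CL.

Between-subject variability is log-normal on CL, Vc and Vp
(Pᵢ = TV·exp(ηᵢ)); Q carries no random effect, because sparse ICU data of
the kind emulated here do not support it.  IIV is reported as a CV in
percent with the exact log-normal conversion ω² = ln(1 + (CV/100)²); its
inverse is used for reporting, so round-trips are exact and the common
shorthand √ω² ≈ CV holds for small ω.  Residual error is proportional by
default (σ_prop as a fraction of the prediction); additive and combined
models are available.  A residual SD of zero is permitted in model
*specifications* (it makes simulation deterministic, which the generator
tests exploit) but rejected by the estimator, which needs positive residual
variance.

Covariate effects are multiplicative factors on CL or Vc: linear
`1 + θ(x − x₀)`, power `(x/x₀)^θ`, exponential `exp(θ(x − x₀))`, and
categorical `1 + θ·1[x = c]`.  Centering values default to the emulated
cohort's medians (weight 80 kg, total bilirubin 2.64 mg/dL, eGFR
68.8 mL/min, MELD 18) and are configurable per effect; a missing covariate
raises rather than imputes, and any factor product that drives a parameter
non-positive over the data is an error, not a clipped value.

### Named models

* **base** — no covariates.  Typical CL carries two presets, 8.6 L/h
  ("headline") and 7.52 L/h ("final_model"), because both values are
  reported for this population in different contexts.  Default IIV: CL
  48.2%, Vc 85% (the reported base-model estimates); Vp 40% is a package
  default in the range typical for sparse ICU data (this η was heavily
  shrunk and its magnitude is not separately reported).  Vc 80 L, Q 60 L/h,
  Vp 250 L are package defaults consistent with tigecycline's large
  distribution volume; they matter only as generating conditions, not as
  reproduced estimates.
* **A** — Child–Pugh class on CL (categorical) + weight on Vc (linear).
  The class enters as a single dichotomous C-vs-A/B indicator with
  θ = −0.501 (the reported 50.1% clearance reduction), because that is how
  the result is reported; a two-indicator (B and C vs A) variant sits
  behind a flag, with a package-default B coefficient.  The likelihood-ratio
  df for the dichotomous default is 1.
* **B** — MELD on CL (power, package-default θ = −0.5) + weight on Vc.
* **C** — eGFR (linear) and total bilirubin (power) on CL + weight on Vc.
  The eGFR coefficient 0.00489/mL·min⁻¹ and typical CL 7.52 L/h are
  back-calculated from the reported clearance range over the observed eGFR
  span (5.62–10.5 L/h across 17.2–149.8 mL/min) — the two constraints
  solve exactly to these values.  The bilirubin exponent −0.213 is derived
  the same way from the reported 4.15–11.0 L/h range over 0.19–18.6 mg/dL;
  the two printed ranges are not perfectly mutually consistent, so the
  endpoint-ratio solution is used.
* Weight-on-Vc: 0.0125/kg around 80 kg, a package default of typical
  pharmacometric size (the source reports significance and IIV reduction
  but not the coefficient).

## Estimation

The per-subject marginal likelihood is approximated by the Laplace method at
the conditional mode η̂ of

g(η) = Σⱼ [log vⱼ(η) + (yⱼ − fⱼ(η))²/vⱼ(η)] + ηᵀΩ⁻¹η + log det Ω,

with the residual variance v evaluated at the individual prediction (the
FOCE "interaction" convention).  The subject's OFV contribution is
g(η̂) + log det(½∇²g(η̂)); the n·log 2π data constant is omitted, matching
the NONMEM convention so OFV differences are comparable with published
ΔOFV values.  With all ω² = 0 this reduces to the fixed-effects
weighted-least-squares deviance; a subject with no observations contributes
exactly 0.

*Inner problem.*  The conditional modes for all subjects are found
simultaneously by a damped Newton iteration vectorized across the cohort.
Gradients of g use complex-step differentiation of the closed-form model
(machine precision, no step-size tuning); Hessians are one-sided finite
differences of those gradients, eigenvalue-floored for positive
definiteness, with steps trust-region-capped at norm 3 on the log scale and
backtracked.  Convergence: max |∇g| < 1e−8.  The same Hessian supplies the
Laplace log-determinant.  Against an adaptive Gauss–Hermite oracle
(64 nodes per dimension, centred and scaled at the mode) the approximation
agrees to < 0.1 OFV units on informative 1–2-η toys; with very sparse data
per subject the Laplace error grows, as expected of any FOCE-class method.

*Outer problem.*  Structural parameters, ω² and σ are optimized on the log
scale (covariate coefficients untransformed) by L-BFGS-B with numerical
gradients (relative tolerance 1e−9, bound ω² ≥ 1e−6 serving as the "zero"
boundary), warm-starting the inner modes between objective calls; a
Nelder-Mead fallback runs when L-BFGS-B fails.  Invalid parameter regions
(e.g. a linear covariate effect turning CL negative for some subject)
return a large penalty value.  Non-convergence flags the result instead of
raising.  Fits are deterministic given data, inits and tolerances.

*Diagnostics.*  η-shrinkage is 100·(1 − SD(η̂)/ω) with the n−1 SD
denominator (the convention is not universal; this matches common NONMEM
reporting).  AIC = OFV + 2·#parameters.  Likelihood-ratio p-values are
χ²(df) upper tails of max(ΔOFV, 0).

*Stepwise covariate modeling* follows the classical forward-inclusion
(α = 0.05) / backward-elimination (α = 0.01) scheme, one effect per round,
ties broken by larger ΔOFV then candidate order, non-converged candidates
skipped and logged.  The trace records IIV on CL and Vc before and after
every step and flags effects cutting IIV_CL by more than 10 percentage
points — the extra criterion used to shortlist covariates for dose
adjustment.

*pc-VPC.*  Observations and simulated replicates are scaled by (bin-median
population prediction / record's population prediction), binned equal-count
on time-after-dose (default 5 bins, 500 simulations), and summarised as
5th/50th/95th percentiles with a 95% simulation band per percentile.
Records with zero population prediction are excluded with a warning.

*Uncertainty.*  Parameter uncertainty uses a nonparametric bootstrap
(subjects resampled with replacement, full refits, 2.5/50/97.5 percentile
intervals, ≥ 50 replicates, flagged unreliable above 20% non-convergence).
This replaces the log-likelihood-profiling/SIR routine of the emulated
analysis — a deliberate simplification: the bootstrap is assumption-light
and test-friendly, at the cost of optimistic behaviour in very small
cohorts.

## Synthetic cohort

The generator emulates the study design: default 39 subjects, 100 mg
loading dose over 30 min then 50 mg q12h (8 subjects at 100 mg q12h),
samples at 0.3, 2, 5, 8 and 11.5 h after the start of an infusion at least
36 h into therapy.  Sampling occasions: every subject contributes one
occasion at 36 h; the first 18 subjects contribute a second at 60 h, making
the expected total 285 ≈ 283 observations (the reported count implies
~7.3 samples/subject, i.e. some subjects were sampled on two occasions; the
exact split is not reported).  "0.3 h after infusion" is interpreted as
after infusion *start*; the wording is ambiguous and the interpretation is
configurable.

Continuous covariates are truncated log-normals calibrated so the sample
medians at n = 39 sit within 15% of the study's descriptive medians at the
calibration seeds, with hard min–max truncation at the reported ranges.
Bilirubin, INR, albumin, ascites grade, creatinine and LiMAx share a latent
"liver severity" factor (loadings in `cohort._COVARIATE_CALIBRATION`), so
the derived scores spread realistically and covariates correlate the way
liver disease makes them correlate.  Child–Pugh points (closed lower bounds
on the middle bands, encephalopathy fixed at "none" + 1 point), MELD
(pre-2016 UNOS form, no sodium term, inputs floored at 1, creatinine capped
at 4 mg/dL) and eGFR (CKD-EPI 2009, no race coefficient) are always
*derived* from the drawn components, never sampled, so patients are
internally consistent by construction.

Two reported marginals cannot all be honoured simultaneously: the study's
ascites counts (7/16/16 none/grade 1/grade 2) are arithmetically
incompatible with its predominantly class-A/B Child–Pugh mix under the
published scoring rule (grade-2 ascites plus the encephalopathy point alone
reaches 7 points = class B), and the reported median eGFR (68.8) exceeds
what CKD-EPI yields at the reported median creatinine/age/sex mix (~55–60).
The generator resolves both in favour of internal consistency: ascites
thresholds are a compromise (≈16/17/6 marginal, ≈15 A / 19 B / 5 C classes)
and eGFR is always the CKD-EPI value of the drawn creatinine.  Albumin has
no reported distribution; the default (median 3.55 g/dL, truncated
1.5–4.5) was chosen once to support the class-A-rich mix and is on the
high side for an ICU cohort.

What passing tests show — and don't.  Recovery experiments demonstrate that
the estimator is consistent under the model's own assumptions (log-normal
IIV, proportional error, correctly specified structure).  Real TDM data add
model misspecification, occasion-to-occasion variability, recording errors
and adaptive sampling, none of which the generator emulates; passing
recovery therefore validates the machinery, not the clinical conclusions.

## Monte Carlo dose adjustment and PTA

Virtual subjects resample whole covariate vectors with replacement from a
patient pool (per-covariate independent resampling would destroy the
correlations the adjustment rules key on).  Exposure per subject is the
analytic steady-state AUC over 24 h (daily maintenance dose / individual
CL — exact for linear elimination) and the closed-form infinite-train
steady-state trough.  Dose-adjustment rules reduce the maintenance dose to
25 mg q12h when a covariate crosses its cutoff (defaults: Child–Pugh class
C, MELD ≥ 30, bilirubin ≥ 10 mg/dL, eGFR ≤ 30 mL/min; the eGFR direction
is printed both as < and ≤ in the source — ≤ is the default,
configurable).  Strategies are scored primarily by the percentage of the
pooled population inside the reference interval, with the absolute relative
deviation of the pooled median from the reference median as tie-break; the
source combines the two criteria without a stated weighting, so this
primary/tie-break scheme is a declared choice.  The reference exposure
range (high-dose tigecycline in non-ICU patients) is printed in two
slightly different versions; (10.12, 5.3–17.4) is the default and
(10.1, 5.28–17.1) a named preset.  PTA uses a two-fold MIC grid
0.03125–8 mg/L and the AUC/MIC targets 6.96 (cIAI) and 17.9 (cSSI);
PTA₉₀ is the largest grid MIC keeping PTA ≥ 90%.

## Experiment sizes

The recovery experiments use 10 replicate cohorts of 100 subjects × 12
samples (base model) and 150 subjects stratified to ~20% Child–Pugh C
(Model A), refitted from deliberately off-truth generic initial values;
the PTA simulation uses n = 1000 subjects.  These sizes give Monte Carlo
error comfortably inside the comparison tolerances while keeping a full
acceptance run around ten minutes on one CPU.

## Known limitations

* FOCE/Laplace bias on very sparse designs is inherited by construction;
  no SAEM or importance-sampling estimator is provided.
* No inter-occasion variability, correlated random effects, BLQ/censoring
  handling, saturable elimination or covariance-step standard errors
  (bootstrap only).
* The stepwise search carries the usual selection-bias caveats of SCM.
* The reference exposure range enters only as published numbers; the model
  generating it is not reimplemented.
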