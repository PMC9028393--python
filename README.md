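# tigepk

Population pharmacokinetics of **tigecycline in critically ill patients with
liver impairment**: a nonlinear mixed-effects modeling and simulation toolkit
for evaluating covariate-guided dose adjustment.

Tigecycline is a last-resort antibiotic that is substantially eliminated by
the liver.  In ICU patients with acute or chronic hepatic dysfunction its
clearance can fall to roughly half of that in other populations, so the
standard maintenance dose (50 mg q12h after a 100 mg load) can overexpose
the sickest patients.  This package implements the full analysis pipeline a
pharmacometrician would use to study that problem on sparse therapeutic-drug-
monitoring data:

* **Structural model** — two-compartment disposition with zero-order
  (infusion) input and linear elimination, solved in closed biexponential
  form.  With micro-constants k10 = CL/Vc, k12 = Q/Vc, k21 = Q/Vp, the
  macro rates are the roots of λ² − (k10+k12+k21)λ + k10·k21 = 0 and the
  concentration is a superposition of single-infusion terms.
* **Statistical model** — log-normal inter-individual variability (IIV) on
  CL, Vc and Vp (Pᵢ = TV·e^η, η ~ N(0, ω²), reported as CV%), a proportional
  residual error model, and multiplicative covariate effects (linear, power,
  exponential, categorical) on CL and Vc.
* **Estimation** — a Laplace / FOCE-with-interaction approximation of the
  marginal likelihood at the conditional η modes, with the NONMEM objective
  function convention (−2·log L without the n·log 2π constant), so ΔOFV
  values compare directly with published tables.  Empirical Bayes estimates,
  η-shrinkage, AIC, likelihood-ratio tests, forward-inclusion /
  backward-elimination covariate search (p < 0.05 in, p < 0.01 to stay),
  prediction-corrected VPCs and nonparametric bootstrap intervals.
* **Dose-adjustment simulation** — Monte Carlo cohorts resampled as whole
  covariate vectors (preserving correlations), steady-state exposure
  AUCss = daily dose / CL and closed-form troughs, dose-reduction rules
  triggered by Child–Pugh class C, MELD, total bilirubin or eGFR cutoffs,
  scored against a published high-dose reference exposure range, and
  probability of target attainment, PTA(MIC) = P(AUCss/MIC ≥ target), with
  the tigecycline targets 6.96 (cIAI) and 17.9 (cSSI).
* **Synthetic cohort** — a generator reproducing the study design this
  package emulates (39 ICU patients, sparse samples at 0.3/2/5/8/11.5 h
  after an infusion ≥ 36 h into therapy, ≈283 observations) with internally
  consistent Child–Pugh, MELD and CKD-EPI scores computed from the drawn
  components.

## Worked example

```python
from tigepk import base_model, model_a
from tigepk.cohort import CohortDesign, generate_cohort, covariate_pool, STANDARD_REGIMEN
from tigepk.dosing import (simulate_cohort, evaluate_adjustment, pta_curve,
                           pta90_mic, STUDY_RULES, REFERENCE_HIGH_DOSE_NON_ICU,
                           TARGET_CIAI)

patients = generate_cohort(CohortDesign(), seed=1)
pool = covariate_pool(patients)

summary = simulate_cohort(base_model(), pool, STANDARD_REGIMEN, n=1000, seed=1,
                          reference=REFERENCE_HIGH_DOSE_NON_ICU)
print(summary.percentiles())            # {'p2.5': 4.59, 'median': 11.94, 'p97.5': 28.62}
print(summary.fraction_in_reference)    # 75.3

rep = evaluate_adjustment(STUDY_RULES["cps_c"], model_a(), pool, n=1000, seed=1)
print(rep["fraction_in_reference_unadjusted"])  # 71.8
print(rep["fraction_in_reference_adjusted"])    # 75.3

print(pta90_mic(pta_curve(summary.auc, TARGET_CIAI)))  # 0.5
```

Reading the numbers: under standard dosing the simulated cohort's
steady-state AUC is 11.9 mg·h/L in median but spreads 4.6–28.6 mg·h/L
(2.5th–97.5th percentile) — wider than the 5.3–17.4 mg·h/L reference band of
high-dose tigecycline in non-critically-ill patients, which is why only ~72%
of subjects fall inside it when severe-liver-impairment patients are not
dose-reduced.  Switching Child–Pugh C patients to 25 mg q12h pulls their
exposure back into the band and raises the in-range fraction.  The last line
says the standard regimen keeps ≥ 90% target attainment for the
intra-abdominal-infection target up to an MIC of 0.5 mg/L.

A command-line surface wraps the same pipeline:

```bash
tigepk synth --n 39 --seed 1 --out run
tigepk fit --out run
tigepk simulate --rule cps_c --out run
tigepk pta --target ciai --out run
```

Each command logs the package version, config hash and seeds into
`run/run.log`; identical configs give bit-identical outputs.

## Layout

| module | contents |
| --- | --- |
| `tigepk.pk_core` | closed-form two-compartment kinetics, regimens, steady-state exposure |
| `tigepk.popmodel` | population parameters, covariate effects, candidate models base/A/B/C |
| `tigepk.estimation` | Laplace/FOCE-I OFV, fitting, EBEs, shrinkage, LRT, SCM, pc-VPC, bootstrap |
| `tigepk.dosing` | Monte Carlo exposure, dose-adjustment rules, cutoff search, PTA |
| `tigepk.cohort` | virtual patients, clinical scores (Child–Pugh, MELD, CKD-EPI), study designs |
| `tigepk.dataio` | NONMEM-style CSV datasets, validated run configuration |
| `tigepk.cli` | `tigepk` command-line pipeline |
| `tigepk.experiments` | reproducible recovery / PTA experiments used by the acceptance script |

See `docs/methods.md` for the modeling assumptions, numerical choices and
known limitations.
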