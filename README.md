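# nutribias

Self-reported nutrition intake is systematically misreported, and the error
is not random: people with high true intake tend to under-report more. A
common countermeasure in nutrition epidemiology is the **Goldberg cutoffs** —
exclude participants whose reported energy intake is implausible relative to
their predicted energy expenditure — before estimating either mean intake or
intake–outcome associations. `nutribias` implements that screening rule, a
reporting-error model fitted from paired self-report/biomarker data, and a
plasmode-style Monte-Carlo study that measures how much association bias the
screening actually removes. A calibrated synthetic cohort generator stands in
for restricted biomarker datasets, so the whole pipeline runs out of the box.

The package is aimed at nutrition epidemiologists and biostatisticians who
want to quantify, for their own data structure, whether excluding extreme
reporters buys them unbiased association estimates — or merely unbiased
means.

## The model

For each nutrient (energy EI in kcal/d, sodium SI and potassium PoI in mg/d,
protein PrI in g/d) a participant has a biomarker intake `NI_BIO` (doubly
labeled water for energy, 24-hr urine otherwise) and a self-report `NI_SR`.

**Screening.** Predicted expenditure is `EE = PAL × BMR` with
`BMR = 370 + 21.6 × FFM` (kcal/d, FFM = fat-free mass in kg, PAL = 1.75).
A report is plausible when

```
exp(−2S/100) < EI_SR / EE < exp(+2S/100),
S = sqrt(CV_wEI²/d + CV_wB² + CV_tP²)
```

with CVs 23, 8.5 and 15 percent and d = 7 assessment days by default
(S ≈ 19.3, bounds ≈ 0.68–1.47). Screening uses energy only; exclusions
propagate to all nutrients.

**Reporting error.** `NI_SR = NI_BIO + e`, with
`e ~ N(μ(p(NI_BIO)), σ²)` where p is the Hazen percentile of the biomarker
value in a fixed reference cohort and `μ(p) = Σ m_k p^k` is a polynomial
whose order K ∈ {1..5} is selected by 10-fold cross-validation. Constant σ is
checked with a Goldfeld–Quandt variance-ratio test.

**Simulation.** Each replicate resamples (FFM, biomarkers) jointly from a
source cohort (n = 100 per replicate, 1000 replicates by default), generates
outcomes `HO = a₀ + a₁·NI_BIO + N(0, η²)` and self-reports from the fitted
models, applies the cutoffs, and fits outcome-on-intake OLS slopes three
ways: on biomarker intake (BIO), on self-report (SR), and on the accepted
subset (G). Performance per estimator over replicates:

```
Bias = mean(β̂) − β₁
MSE  = (1/n) Σ (β̂ᵢ − mean β̂)² + Bias²
P    = fraction of replicates with ci_low < β₁ < ci_high
```

Empirically, the percent bias `b = (β_SR − β_BIO)/β_BIO × 100` and percent
remaining bias `r = (β_G − β_BIO)/β_BIO × 100` get leave-one-out jackknife
CIs.

## Worked example

```python
import numpy as np
from nutribias import CohortConfig, generate, screen_cohort, fit_source_models
from nutribias import SimulationConfig, run_simulation, summarize_simulation

cohort, truth = generate(CohortConfig(n=303), seed=1)
accepted, rejected, _ = screen_cohort(cohort)
print(f"accepted {len(accepted)}, rejected {len(rejected)}")

rng = np.random.default_rng(1)
error_models, outcome_models = fit_source_models(cohort, rng=rng)
print("selected polynomial orders:", {k: m.order for k, m in error_models.items()})

cfg = SimulationConfig(n_individuals=100, n_replicates=1000,
                       nutrients=("EI",), outcomes=("BW",))
results = run_simulation(cohort, error_models, outcome_models, cfg, rng=rng)
beta1 = {k: m.a1 for k, m in outcome_models.items()}
print(summarize_simulation(results, beta1).round(4).to_string(index=False))
```

prints (seed 1):

```
accepted 208, rejected 95
selected polynomial orders: {'EI': 1, 'SI': 3, 'PoI': 3, 'PrI': 1}
nutrient outcome estimator    bias    mse  coverage  beta1  n_replicates_used
      EI      BW       BIO -0.0001 0.0000     0.956 0.0153               1000
      EI      BW        SR -0.0133 0.0002     0.000 0.0153               1000
      EI      BW         G -0.0103 0.0001     0.261 0.0153               1000
```

Read: about a third of the synthetic cohort is excluded by the cutoffs (the
same order as real biomarker studies); the self-report slope for energy vs
body weight is attenuated almost to zero (bias −0.0133 against a true slope
0.0153, coverage 0%), and screening recovers only part of it (bias −0.0103,
coverage 26%) — exclusion of extreme reporters narrows but does not close
the gap to the biomarker benchmark. The biomarker arm itself is unbiased
with nominal 95% coverage. Cross-validated order selection is itself
sampling-variable at n = 303: this particular draw picks orders 1, 3, 3, 1
against generating truths 1, 3, 3, 5, though across many seeds the true
orders win the majority (see the test suite).

The same pipeline is available from the shell:

```
nutribias all --n-cohort 303 --n 100 --replicates 1000 --seed 1 --out results/
```

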