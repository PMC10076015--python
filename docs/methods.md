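# Methods

This note documents the statistical machinery in `nutribias`: the screening
rule, the reporting-error model, the synthetic cohort generator and its
calibration, the Monte-Carlo design, and the numerical choices made where
the design was genuinely open.

## Goldberg screening

Basal metabolic rate is predicted from fat-free mass, `BMR = 370 + 21.6 ×
FFM` (kcal/day), and expenditure as `EE = PAL × BMR` with PAL = 1.75.
Reported energy intake is plausible when `EI_SR/EE` lies strictly inside
`exp(∓2S/100)`, where `S = sqrt(CV_wEI²/d + CV_wB² + CV_tP²)` aggregates the
within-subject CV of reported intake (23%, shrunk by d = 7 assessment days),
of BMR (8.5%) and the total CV of PAL (15%); the defaults give S ≈ 19.31 and
bounds ≈ (0.6796, 1.4714). A ratio exactly on a bound is rejected — the
interval is read literally as a strict double inequality. Screening is
computed on energy intake only and the exclusion propagates to every
nutrient's accepted set. Classification depends only on the individual's own
values, which is what makes leave-one-out resampling downstream well defined
(re-screening a leave-one-out subset is a no-op).

Rows missing FFM or EI_SR cannot be classified; `screen_cohort` drops them
from both partitions with a logged count rather than guessing.

## Reporting-error model

For one nutrient the reporting error is `e = NI_SR − NI_BIO`, modelled as
`e ~ N(μ(p), σ²)` with `μ(p) = Σ_{k≤K} m_k p^k` a polynomial in the Hazen
percentile `p = (rank − 0.5)/n` of the biomarker value in a **fixed
reference sample** (the full source cohort, never the resampled subset), so
μ is always evaluated on the scale it was fitted on. Out-of-range values
clamp to the extreme in-sample percentiles; ties take the upper rank.

The order K is selected over candidates 1..5 by 10-fold cross-validation:
folds are a seeded uniform random partition into near-equal parts, the
selected K minimizes the mean out-of-fold squared error, and ties within
1e-10 relative (on the scale of the error variance, so exactly-fit noiseless
data count as ties) resolve to the smaller order. σ is the residual SD with
denominator n − (K + 1). Both conventions (fold construction, σ estimator)
are standard-practice choices; nothing in the underlying design pins them
down.

Homoskedasticity of σ is checked with a Goldfeld–Quandt variance-ratio test:
observations sorted by biomarker intake, the central `round(n × 0.2)`
observations discarded (round half up — 303 × 0.2 = 60.6 → 61), F the ratio
(larger/smaller) of the error variances about the group means in the
high/low groups, p two-sided from the F distribution. The "residuals" are
the raw errors centred by group mean, not regression residuals.

## Synthetic cohort generator

The generator emulates a biomarker-validation cohort of older adults:
marginal means/SDs of FFM, the four biomarker intakes, the per-nutrient
reporting-error mean/SD, body weight and waist circumference are the
published cohort summaries; the error–biomarker correlations are derived
from the published SD triples through
`Cov(e, BIO) = (sd_SR² − sd_BIO² − sd_e²)/2`, giving −0.36 (energy), −0.75
(sodium), −0.64 (potassium), −0.53 (protein) — all negative, i.e. the
higher the true intake, the more negative the reporting error.

Structure of one draw:

1. **(FFM, biomarkers)** come from a 5-dimensional normal truncated at zero
   (rows with any non-positive coordinate are redrawn). The FFM–energy
   correlation (0.6) and the cross-nutrient biomarker correlation (0.5) are
   not published anywhere; they are plausible, configurable defaults.
   Truncation inflates means and shrinks SDs (noticeably for sodium, whose
   mean sits ~2 SD above zero), so the latent mean vector and per-coordinate
   scales are adjusted by a short fixed-point iteration against pilot draws
   (default pilot size 50,000) until the realized truncated moments match
   the targets.
2. **Generating-truth error models** are solved per nutrient in the shifted
   Legendre basis on [0, 1], which is orthogonal under the uniform
   percentile distribution and makes the three calibration constraints
   separable: the basis-0 coefficient is the target mean; the top-degree
   coefficient (orders 1, 3, 3, 5 for EI/SI/PoI/PrI) is fixed at half the
   target error SD; the linear coefficient is solved for the covariance
   target using `g_k = E[q_k(Φ(Z))Z]` (Gauss–Hermite quadrature); σ² takes
   the remaining variance budget. The top-degree amplitude of 0.5·SD was
   chosen a priori by a paired cross-validation power argument: the
   out-of-fold MSE gain of the true order over its neighbour,
   `c_K²/(2K+1)`, must exceed a few times `σ²·sqrt(Var)/n` at n = 303 for
   order selection to recover the truth in the majority of seeds; 0.5 gives
   roughly 1.6–2.2 of those units. Because joint truncation and the SR > 0
   truncation perturb the closed-form solution slightly, the linear
   coefficient and σ are then refined by three fixed-point steps against
   pilot draws so the realized (mean, SD, correlation) triple lands within
   tolerance (0.01 on the correlation).
3. **Self-reports** are `NI_SR = NI_BIO + μ(p) + noise`. The noise has a
   one-factor structure: a person-level shared misreporting factor with
   loading 0.5 plus an idiosyncratic term, so that someone who under-reports
   energy tends to under-report the other nutrients too. The loading leaves
   every nutrient's marginal error distribution unchanged (all calibration
   targets are unaffected) but reproduces the empirical pattern that
   energy-based screening also removes the worst misreporters of sodium,
   potassium and protein. `NI_SR > 0` is enforced by redrawing the
   idiosyncratic noise (up to 100 rounds, then clamping to one unit, logged);
   the small upward mean shift this causes is removed analytically — the
   per-row truncated-normal mean shift `σ·φ(α)/(1−Φ(α))` is averaged and
   subtracted from the constant coefficient, so the mean reporting error
   stays on target.
4. **Outcomes** are linear in one designated nutrient's biomarker intake:
   body weight, waist circumference and heart rate from energy; systolic and
   diastolic pressure from sodium; VO2 max from potassium. Body-weight and
   waist marginals are published; the other outcome marginals and all
   outcome–intake correlations (0.40, 0.45, 0.15, 0.25, 0.20, 0.35) are
   configurable plausible defaults. Intercepts/slopes/residual SDs are
   derived from the marginals, e.g. `a₁ = ρ·sd_HO/sd_BIO`.

What the generator does **not** emulate: demographics and their association
with misreporting, heavy-tailed or heteroskedastic reporting error, and any
nonlinearity in the intake–outcome relationships. Passing tests therefore
show that the pipeline behaves correctly under the calibrated Gaussian,
linear-outcome world — not that real cohorts satisfy those assumptions.

## Monte-Carlo design

Each replicate resamples n = 100 rows **with replacement** (the sensitivity
grid reaches n = 300 from a 303-row source, where without-replacement
sampling would be nearly a permutation), keeping (FFM, all biomarkers)
jointly intact within a row. Per nutrient, self-reports are generated from
the fitted error model with percentiles against the fixed source reference;
the energy self-report is always generated — whether or not energy is being
analysed — because it alone drives the Goldberg classification. Outcome
noise and reporting noise are independent draws; the engine generates each
nutrient's error independently (no shared factor — each nutrient's replicate
is a separate experiment, as in the underlying study design). Per
nutrient–outcome pair the three OLS slopes (BIO, SR, G) are fitted with
t-based 95% CIs (df = n − 2). If fewer than 3 resampled rows are accepted,
the G fit for that replicate is recorded as missing (NaN) and excluded from
metric averaging with a logged count.

Defaults: 1000 replicates, sensitivity grid n ∈ {50, 100, 200, 300}, and
multipliers `sigma_scale`/`eta_scale` on the reporting-error SD and outcome
residual SD. With the default decreasing μ the self-report slope is
attenuated toward zero in every pair; as `sigma_scale → 0` the self-reported
predictor is *compressed* (its variance falls below the biomarker's because
`Cov(e, BIO) < −Var(μ)`) and the association is intensified instead — the
bias flips sign. An *increasing* μ cannot produce that reversal: with
`Cov(e, BIO) > 0` the SR slope ratio `(V + C)/(V + Vμ + 2C)` is below one
for any noise level.

## Performance metrics

Across replicates: `Bias = mean(β̂) − β₁`; `MSE = (1/n)Σ(β̂ᵢ − mean β̂)² +
Bias²` — the population-variance (1/n) convention, which makes MSE equal
`(1/n)Σ(β̂ᵢ − β₁)²` exactly; coverage counts strict inclusion
`ci_low < β₁ < ci_high`. β₁ is the slope fitted on the source cohort (the
"truth" of the plasmode world, not of nature).

Empirical percent bias `b` and percent remaining bias `r` compare the SR and
G slopes to the BIO slope in percent. Their CIs are leave-one-out jackknife:
`SE = sqrt((n−1)/n · Σ(θ̂ᵢ − θ̂·)²)` with a normal-approximation interval
around the full-sample estimate (not percentile-jackknife). The leave-one-out
slopes are computed by exact O(n) downdates of the OLS sufficient statistics
— algebraically identical to refitting, verified against brute-force refits
in the tests. Goldberg classifications are held fixed per individual across
leave-one-out subsets. A pair whose β_BIO is below 1e-12 (relative to the
coefficient scale) is flagged unstable rather than reported as a huge ratio.
Significance flags follow the study's conventions: bias when the b CI
excludes 0, remaining bias when the r CI excludes 0, bias *reduction* when
the r CI lies within (−100, 100). α = 0.05 two-tailed throughout, no
multiplicity adjustment, bivariate regressions only.

## Degenerate inputs and tie-breaks

* Ratio exactly at a Goldberg bound → rejected (strict inequality).
* CV-MSE ties within 1e-10 relative → smaller polynomial order (parsimony).
* Jackknife with a constant statistic → zero-width CI; the whole-vs-accepted
  mean test reports the exact difference with p = 1 when it is zero instead
  of dividing by a zero SE.
* An error-SD target of exactly zero makes the generator emit `NI_SR =
  NI_BIO` (plus any constant shift) — used to verify that the engine's SR
  and BIO arms then coincide replicate by replicate.
* Goldfeld–Quandt with both group variances zero returns F = 1, p = 1.

## Problem sizes

The default test and acceptance runs use a 303-row source cohort, 100,000
participants for generator-calibration checks, 1000 replicates of n = 100
for the Monte-Carlo metrics, and 100 seeded cohorts for the order-recovery
study; these sizes put every Monte-Carlo tolerance (3 SEs unless stated)
well inside a few seconds to tens of seconds of computation.

## Known limitations

* The calibration assumes a truncated-normal biomarker joint; real intake
  distributions are right-skewed, so percentile-conditional error means fit
  on real data may differ in shape from the Legendre truths used here.
* The shared misreporting factor (one factor, loading 0.5) is the simplest
  structure producing cross-nutrient error dependence; the true dependence
  is unknown.
* The jackknife CI relies on the normal approximation; for near-zero
  denominator slopes the percent-bias ratios are heavy-tailed and the CIs
  should be read qualitatively (the unstable flag marks the worst cases).
* Coverage statements concern the plasmode truth β₁; they say nothing about
  covariate-adjusted or nonlinear associations, which are out of scope.
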