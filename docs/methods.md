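# Methods

## Design

The package implements a factorial Mendelian-randomization (MR) analysis
as a tested pipeline over synthetic cohorts. Factorial MR exploits the
independent assortment of genetic variants: median-splitting a cohort on
two independent weighted genetic scores cross-classifies it into four
groups whose membership is effectively randomized, mimicking a 2×2
factorial trial of two interventions (e.g. Lp(a) lowering × LDL-C lowering
via a drug-target gene). Because the biobank data such analyses use are
access-controlled, validation is by parameter recovery on generated
cohorts whose ground truth is recorded in a JSON sidecar, never by
re-computation of any published cohort estimate.

## Generating model

For each score, variants are independent (emulating clumped instruments)
with Hardy–Weinberg dosages `g_ij ~ Binomial(2, p_j)`. The true score is
`S_i = Σ_j g_ij β_j` in trait units. Measured biomarkers are linear in the
true scores:

    Y_i = intercept + Σ_s loading_s · S_is + N(0, σ_noise),

with off-trait loadings encoding cross-trait pleiotropy. Covariates: age
`N(56.7, 8.0)` years, sex Bernoulli(0.46 male), assessment center uniform
over 10 categories, 10 standard-normal principal components.

Survival outcomes follow an exponential proportional-hazards model:

    λ_i = λ0 · exp(Σ_s β_s S_is + γ·(age_i − 56.7) + δ·sex_i
                   + center/PC effects + θ · Z(S_A) Z(S_B)),

where `Z(·)` standardizes by the theoretical Hardy–Weinberg mean and SD and
`θ` is the generating interaction on the product of the two designated
arms. Event times are exponential given the linear predictor, with
administrative censoring at 12.25 years; only incident events are
generated (prevalent-case handling, with its time-origin ambiguity, is
deliberately not emulated). The constant baseline hazard is a choice, not
a limitation of the analysis: Cox estimation is rank-based, so log-HR
recovery is unaffected, and the exponential form gives closed-form event
probabilities for the generator's own tests.

Age enters the hazard centered at its generating mean so that `λ0` remains
interpretable as the event rate of a reference individual; centering only
rescales the baseline hazard and leaves every fitted log-HR unchanged.

One global seed drives everything; per-component substreams (per-score
genotypes, covariates, biomarkers, per-outcome survival) are spawned from
it in a fixed order, so cohorts are byte-identical across reruns and
robust to adding outcomes.

## Calibration of the defaults

The default configuration is calibrated so the synthetic cohort's columns
and contrasts land at published population magnitudes for this design:

- Measured Lp(a): mean 17.6, SD 19.7 mg/dL, decomposed into a genetic
  score SD of 12.33 and noise SD 15.4. A median split of a normal score
  gives an expected lower-vs-higher contrast of `−1.596·SD`, so the
  Lp(a)-score contrast on measured Lp(a) is ≈ −19.7 mg/dL.
- LDL-C (mean 138.0, SD 33.6) and triglycerides (mean 154.9, SD 90.6)
  likewise; drug-target score SDs (HMGCR 1.57, NPC1L1 0.66, PCSK9 1.69,
  LDLR 2.42 mg/dL) were back-computed from the target group contrasts
  (−2.50, −1.06, −2.70, −3.86 mg/dL) by the same `−1.596·SD` identity.
- Pleiotropy: the Lp(a) score loads 0.072 on LDL-C and −0.165 on
  triglycerides, reproducing the weak LDL-C lowering and the TG *increase*
  seen in the genetically-lower-Lp(a) group.
- Outcome effects: per-mg/dL log-HRs for the Lp(a) score are set from
  target per-50-mg/dL-decrease hazard ratios spanning 0.73 (PAD-like) to
  0.95 (VTE-like); baseline hazards (0.004–0.012 events/person-year) give
  5–15% event proportions over follow-up.

The shipped fixture weight tables carry the published instrument
cardinalities (43 Lp(a), 26 HMGCR, 6 NPC1L1, 42 PCSK9, 52 LDLR, 237
overall LDL-C, 62 BMI, 455 SBP, 248 smoking, 98 alcohol, 16 physical
activity) with synthetic frequencies (uniform on 0.05–0.95) and weights
rescaled to the target score SDs; `scripts/make_weight_fixtures.py`
regenerates them from a fixed seed.

What the generator does **not** emulate: linkage disequilibrium between
variants, allele-frequency spectra and strand/harmonization issues of real
GWAS instruments, skewed (non-Gaussian) biomarker distributions — real
Lp(a) is strongly right-skewed while the synthetic version is normal and
can go negative — population stratification beyond abstract PCs,
informative censoring, competing risks, and prevalent disease. Passing
tests therefore establish that the *estimators* are correct under the
assumed data-generating process, not that any biological conclusion
transfers to real cohorts.

## Estimators and conventions

- **Weight tables** are stored trait-increasing; "lowering" appears only
  at analysis time as the sign convention `exp(−50·β̂)`, never by flipping
  weights (a single stored orientation avoids double-negation bugs).
- **Median split**: individuals with score ≤ sample median are "lower";
  ties go to the lower group, keeping allocation deterministic. Medians
  are always computed on the analysis cohort.
- **Factorial reference** is the both-higher cell. For arms where a
  *higher* score is the healthier exposure (physical activity), the CLI
  negates the score before splitting so "both_lower" is always the jointly
  improved arm; this is an analysis-time orientation choice, the weights
  are untouched.
- **Adjustment set** everywhere: age, sex, center one-hot indicators
  dropping the first category, PC1–10. Two-sided tests throughout; 95%
  intervals use z = 1.959964. No multiple-testing adjustment across
  outcomes.
- **Interaction** is operationalized on the log-hazard scale (departure
  from multiplicative combination of HRs) via a product term of the two
  standardized scores inside the Cox linear predictor; standardization
  decouples the interaction coefficient from main-effect scales, and raw
  trait-unit products are available via `standardize=False`. The
  dichotomized 2×2 indicator-product variant is implemented only as the
  comparator in power studies, where it is uniformly weaker.
- **Composites** take the earliest component event; fully censored
  individuals keep the longest recorded follow-up (the shared
  administrative horizon).

## Numerical choices

The Cox engine maximizes the Breslow-tie log partial likelihood by
Newton–Raphson from β = 0 with step-halving on likelihood decrease, at
most 50 iterations. Convergence is declared when max|gradient| < 1e-8 or
the scale-free Newton decrement `gᵀH⁻¹g/2` falls below 1e-10 (the raw
gradient mixes covariate units, so the decrement is the robust criterion
at large n), or when the accepted step is below 1e-10. Standard errors
come from the inverse observed information. "Converged" fits whose
coefficients exceed 15 on the log-hazard scale are re-flagged as monotone
likelihood (perfect separation drives the gradient to zero numerically as
the risk weights saturate, so the gradient test alone cannot catch it).
Ties are handled by Breslow only — generated times are continuous, so ties
are measure-zero; the choice is fixed for bit-reproducibility. Efron
weighting was considered and not implemented. OLS uses a QR solve with
classical standard errors and raises on rank deficiency, naming the
collinear columns.

Score sums over risk sets use the reverse-cumulative identity
`Σ_events S2/S0 = Xᵀ diag(w·A) X`, avoiding any n×p×p intermediate; a fit
with 20,000 rows and ~16 columns takes ~0.1 s, which is what makes the
full-size Monte-Carlo suite affordable.

## Monte-Carlo suite

Suite definitions are plain YAML (`factorialmr/data/suites/`); every rate
is reported with its binomial Monte-Carlo SE, and acceptance bands are
3-SE bands fixed in advance. Desk-scale sizes: recovery at n = 20,000 ×
200 replicates for generating truths HR ∈ {0.70, 0.90, 1.00} per 50
mg/dL; CI calibration at n = 2,000 × 1,000; interaction type-I error at
n = 5,000 × 1,000; power over the interaction grid θ ∈ {0, 0.04, 0.08,
0.12} at n = 5,000 × 400. The grid spans the detectability range at
~1,500 events per replicate (the Wald SE of the product coefficient is
≈ 1/√events ≈ 0.026, putting 80% power near θ ≈ 0.08). Scenario cohorts
use compact instrument sets (12 variants per score) — score SDs, not
variant counts, determine the statistics — and 4 assessment centers.
Replicate seeds are spawned from the scenario seed; non-convergent
replicates are counted and reported, never dropped.

## Known limitations

- Exponential event times mean the proportional-hazards assumption is
  exactly true; the pipeline includes no proportionality diagnostics.
- The per-50-mg/dL scale is refused for non-mg/dL arms rather than
  silently rescaled; lifestyle arms are reported per subgroup (factorial)
  or per SD.
- The factorial additivity baseline (joint log-HR = sum of single-arm
  log-HRs) holds only approximately under coarsened (median-split)
  exposures in a non-collapsible model; at the default effect sizes the
  discrepancy is well inside Monte-Carlo error, which the suite verifies
  rather than assumes.
- Linear-regression instrument checks use homoskedastic SEs, consistent
  with the generating model but not robust to variance heterogeneity in
  real data.
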