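# Methods

This note documents the models, the synthetic-data generator, the numerical
choices, and the limits of what the test suite demonstrates.

## Study design implemented

The package implements a population-control carrier association design for
an X-linked gene. Subjects are grouped by variant class (pathogenic,
conflicting interpretation, uncertain significance, plus individually
analyzed common variants, each class carrying a `_P`/`_C`/`_U` suffix).
Hemizygous males are compared with male wild-type controls and heterozygous
females with female controls; homozygous females are excluded before any
model is fitted (they are counted and reported separately), and controls
must carry zero alleles across *every* analyzed group. The sex split exists
because X-linked dosage makes male and female carriers biologically
different exposures; X-chromosome inactivation further dilutes effects in
heterozygous females.

## FDF score

Four domains — pain, renal, cardiac, cerebrovascular — each capped at 4
points:

* **Renal** (lab-based): points are the maximum of an eGFR band
  (≥ 90 → 0, 60–89 → 1, 30–59 → 2, < 30 → 4 mL/min) and a uACR band
  (< 30 → 0, 30–300 → 1, > 300 → 4 mg/g). The bands follow KDIGO-style
  staging compressed onto a 0–4 scale. Both components are also exposed
  separately (`egfr_points`, `uacr_points`) for per-component association
  analyses. A missing component makes the domain, and hence the total,
  missing: renal labs are never imputed, and such subjects drop out of any
  model that needs the score (complete-case handling).
* **Cardiac / cerebrovascular** (ICD-based): the code registry assigns each
  matching ICD-10 prefix a severity level (1 = moderate, e.g. arrhythmia,
  TIA; 2 = severe, e.g. cardiomyopathy, heart failure, stroke), and the
  domain scores the *highest* severity seen (levels map to 0/2/4 points —
  max, never a sum).
* **Pain** (questionnaire): the highest reported ordinal response maps to
  points (0/1/2/4); a subject with *every* item missing scores 0 with an
  `imputed` flag. This lowest-category imputation is deliberate and
  one-sided: it can only underestimate the total score.

The total (0–16) is dichotomized at **> 4**. Because no single domain can
exceed 4, a high flag provably requires at least two involved domains; the
test suite checks this exhaustively over all 5⁴ domain-score tuples. The
Youden-index scan over midpoints of adjacent observed scores
(`youden_cutoff`) supports the threshold choice; on real data the optimum
was reported near 4.4, which we keep only as a reference constant — it is a
property of the restricted cohort, not something synthetic data should
reproduce.

The exact item derivation of the original score is not public; the shipped
registry, bands, and weights are therefore explicit, editable
reconstructions (YAML config), not hard-coded claims about the original
instrument.

## CV risk score

A logistic regression of the dichotomized FDF flag on age plus the five
ICD-derived risk-factor flags (diabetes, dyslipidemia, hypertension,
obesity, smoking). The per-subject score is the **linear predictor** — the
log-odds scale is the only one on which the reference threshold of 1.92 is
meaningful. The model is *fitted* on the FD phenotype and *validated* by
its ability to discriminate pathogenic-variant carriers (ROC); the outcome
is config-overridable. Stratification cuts at the empirical 75th percentile
of the reference population's scores, computed once and reused for carrier
subsets; the comparison is strict (`score > q75`), so ties and everyone at
the percentile fall to the low stratum. AUC uses the midrank Mann–Whitney
formulation, which equals the trapezoidal area under the empirical ROC
curve (tested against an independent implementation).

## Association engine

* Logistic (ML, statsmodels `Logit`) for binary outcomes; effect = exp of
  the exposure coefficient. Separation is detected (non-finite SEs or
  |β| > 15) and returned as a flagged result with an unbounded interval
  rather than an exception — at realistic carrier frequencies, small
  cohorts legitimately produce zero carrier events.
* Proportional-odds (statsmodels `OrderedModel`, logit link, BFGS) for
  multi-level domain scores; on a two-level outcome it reproduces the
  logistic OR (tested to 0.1% relative).
* OLS for continuous traits, with `statin_use` added to the covariates for
  lipid traits; carrier and control mean ± SD accompany each fit for
  trait-table output.
* All adjusted models share the six-covariate set (age linear + five binary
  flags). Every model drops rows with any missing outcome/predictor and
  reports the count.
* Intervals are Wald 95% two-sided, i.e. endpoints at the 2.5/97.5 percent
  points of the coefficient's sampling distribution, exponentiated where
  the effect is an OR.
* Benjamini–Hochberg is implemented from scratch
  (`adj₍ᵢ₎ = min_{j≥i} p₍ⱼ₎·m/j`, capped at 1) and validated against a
  brute-force step-up enumeration; one BH pass covers the combined
  adjusted-association and trait p-values, and the stratified analysis set
  receives its own pass.
* VIFs are computed by hand as 1/(1−R²) from regressing each predictor on
  the others (intercept included), with an infinite-VIF marker under exact
  collinearity; they are cross-checked against statsmodels.

Stratified analyses follow the published design: carriers within one CV
stratum versus the *full* same-sex control population, CV-unadjusted. This
asymmetry (stratified cases, marginal controls) is what makes the
interaction pattern so visible: low-stratum carriers are compared against
controls that include the high-risk quarter of the population.

## Synthetic cohort generator

Per-domain event liability:

```
logit P(event_d) = b0_d + 0.04·(age − 57) + log(1.8)·(# risk factors)
                   + carrier·(β_main + β_int·high_CV)·a(sex)
```

with `high_CV` the top quartile of the age + risk-factor part of the
liability and `a(sex)` = 1 for males, the X-inactivation attenuation
(default 0.5) for females. Defaults:

| quantity | default | rationale |
|---|---|---|
| carrier allele frequencies | per published per-sex carrier proportions (e.g. conflicting class 0.0075, pathogenic class 0.00014) | male carrier proportion ≈ allele frequency; female heterozygote fraction ≈ 2p under Hardy–Weinberg, matching the printed female proportions |
| risk-factor prevalence | hypertension 0.27, dyslipidemia 0.15, smoking 0.11, obesity 0.08, diabetes 0.06 | typical middle-aged ICD-coded biobank prevalences |
| domain intercepts | cardiac −3.57, renal −4.05, cerebrovascular −4.28, pain −3.33 | control prevalences near 4 / 2.5 / 2 / 5 % |
| pathogenic effect | β_main = log 5, β_int = 0, uACR ×4 (males) | unconditional multi-organ effect; the ×4 uACR shift matches the published male carrier/control contrast, attenuated through the same X-inactivation exponent in females (whose published uACR contrast is near null) |
| non-pathogenic effect | β_main = log 0.8, β_int = log 2.5 | reproduces the reported pattern: no (or slightly inverse) association at low CV risk, FD-like phenotype only under high CV burden |
| age | Uniform(40, 70) years | biobank recruitment window |
| missingness | pain items 0.7; urinary labs 0.25; BP 0.05; other labs 0.03 | pain questionnaires and urine assays are the sparsest real fields |

No quantitative generative effect sizes exist in the source material (only
fitted ORs on restricted data), so these are one-time calibration choices,
stated here and not tuned afterwards. Labs are per-sex normal (truncated to
positive support) or, for right-skewed analytes (uACR, urinary creatinine,
triglycerides, Lp(a)), log-normal with moments matched to the target
mean ± SD. Urinary albumin is derived as uACR × urinary creatinine (unit
conversion via the 113.12 g/mol creatinine molar mass) with 20% log-normal
noise, keeping the three mutually consistent. Renal-domain events redraw
eGFR (≈ 52 ± 16) and uACR (log-normal, mean ≈ 120) from a diseased
calibration and emit an `N18*` code. Variant groups are drawn
independently; the real-world nesting of individual variants inside their
classes is not modelled, and controls are defined as zero alleles across
all groups.

What the generator does **not** emulate: linkage between variants,
per-tissue X-inactivation mosaics (a single attenuation scalar stands in),
age-dependent risk-factor onset, informative (non-random) missingness,
correlated lab panels beyond the urinary triplet, ICD coding error, and
longitudinal follow-up. Consequently, passing tests demonstrate that the
*analysis machinery* recovers known generative truths under the stated
liability structure — not that the pipeline is robust to every
real-biobank pathology.

## Validation experiments and problem sizes

`fabrykit.experiments.recovery_and_pattern_experiment` runs 20 replicate
cohorts of 200,000 males + 20,000 females at default parameters and, per
replicate:

* **Effect recovery** — fits the CV-adjusted logistic model for
  hemizygous pathogenic males on the *cardiac domain event*. On a single
  domain the fitted model is exactly the generating model, so the true
  conditional OR is exactly 5; on the composite FDF > 4 outcome the
  implied OR is larger than 5 (crossing the two-domain threshold compounds
  the per-domain effect), which is why the composite is not the recovery
  target. Acceptance expects ≥ 15/20 intervals to cover 5 (~95% nominal
  coverage at wide, low-event-count intervals).
* **Interaction pattern** — stratifies by the fitted CV score and expects
  the conflicting-class males to show OR > 1 in the high stratum and
  OR ≤ 1 in the low stratum in ≥ 18/20 replicates.

Unit tests use 5–40k cohorts with inflated carrier frequencies (a test
input choice, to have carriers to exercise the machinery); binomial/SE
tolerances are set at 4 SDs throughout. The replicate experiment takes
roughly a minute per 20 replicates on one CPU; these sizes were chosen as
the smallest at which the coverage and pattern statements are statistically
meaningful.

## Numerical and degenerate-input choices

* Youden threshold: midpoints of adjacent distinct scores; ties broken
  toward the lower threshold; errors on single-class labels or constant
  scores.
* Stratification with all-equal scores: everyone low, with a warning
  (strict inequality contract).
* Proportion rounding in summary tables: decimal half-even at the printed
  digit count.
* BH input validation rejects NaN and out-of-range p-values; callers
  substitute 1.0 for separation-flagged models before adjustment and null
  out those adjusted values afterwards.
* Logistic/ordinal convergence: Newton (logistic) / BFGS (ordinal) with
  raised iteration caps; convergence warnings are suppressed inside the
  fit wrappers because the separation check afterwards is the authoritative
  guard.
* Determinism: every stochastic step draws from one `numpy` Generator
  seeded from the config; equal (config, seed) pairs produce byte-identical
  TSV output (tested via checksums).

## Known limitations

* The ordinal engine fits each domain score's proportional-odds model
  without testing the proportional-odds assumption.
* Wald intervals are used everywhere; profile-likelihood intervals would
  behave better at very low carrier counts (where we instead flag
  separation).
* The published AUC 0.80 / sensitivity 0.77 / specificity 0.70 at
  threshold 1.92, and the Youden optimum 4.4, are properties of the
  restricted cohort; they ship as reference constants and evaluation
  hooks, not as assertions on synthetic data.
* The code registry and scoring map are reconstructions; analyses of real
  data should review and override them via the config file.
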