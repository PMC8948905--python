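# Methods

## Scoring model

Both scores are deterministic rule systems over ordinal categories
(low < moderate < high). Each parameter's rule is a total function on its
admissible domain: numeric parameters use ordered bands closed on the printed
upper bound, categorical parameters use explicit case tables. Treating bands
as `(previous bound, bound]` resolves inputs that fall between printed
integer bounds (a BOP of 9.5% is moderate): the printed ranges otherwise
leave non-integer values unmapped. Out-of-domain values (BOP above 100%,
negative or fractional counts) are errors, never clamped or imputed —
the scores are meant for complete, validated charts.

Aggregation: overall risk is high with at least two high-risk parameters,
low with none high and at most one moderate, and moderate otherwise. The
published prose defines low, high, and two moderate clauses but is silent on
two combinations: one high with at most one moderate (for PRA), and one high
plus exactly one moderate (for either score). Both are assigned moderate
here, extending the explicit clause that one high-risk parameter with all
others low is moderate; this is the minimal monotone completion, and the
test suite checks the resulting function is monotone in every parameter over
all 3^6 and 3^8 combinations.

Other genuinely open points, and the choices made:

- **Periodontitis susceptibility.** The table lists "I A" as low,
  "II A/B, III A/B" as moderate and "III C, IV" as high. Unlisted
  combinations: grade C escalates to high at any stage ≥ II (consistent with
  III C being high while III A/B is moderate); stage I stays low at any grade
  (stage I is by definition early disease). Stage IV is high at any grade.
- **History of stage II–IV periodontitis** never maps to high and
  **compliance** and **RM–bone** never map to moderate: these rows have only
  two levels by construction.
- **Smoking in the IRA.** The IRA has no standalone smoking row; smoking
  enters only through periodontitis grading. No extra parameter is added.
- **RM–bone with a missing measurement.** A tissue-level implant with no
  recorded restoration-margin distance is low risk (the categorization is by
  implant type); a recorded distance < 1.5 mm, or a bone-level implant, is
  high risk.
- **Multi-implant patients.** The scoring implant is the lexicographic
  maximum on (RM–bone category, prosthesis/plaque category), ties broken by
  smallest implant id so repeated runs pick the same implant.
- **Case definition boundaries** are inclusive: PPD ≥ 6 mm, bone level
  ≥ 3 mm. The follow-up event flag is an input (an implant lost to
  peri-implantitis is an event even though it can no longer be probed), and
  the implant-level classifier is the consistency check against recorded
  clinical state, not the source of the flag.

## Synthetic cohort

The generator emulates a periodontally treated implant-maintenance
population of the kind these scores target: default marginals reproduce the
reference cohort's summary table (compliant 83.56%, tissue-level-only
95.89%, periodontitis history 89.04%, smokers 23.29%, BOP 24.29 ± 21.25%,
BL/age 0.59 ± 0.23, tooth loss 8.44 ± 4.24, deep-pocket count 7.85 ± 11.41,
susceptibility split 17.81/68.49/8.22/5.48% across II A/B, III A/B, III C,
IV; 232/73 ≈ 3.18 implants per patient).

Distribution shapes are a modelling choice since only means/SDs and category
fractions are reported: truncated normals for BOP%, BL/age and age;
moment-matched negative binomials for the two counts (both are
over-dispersed; a Poisson fallback covers under-dispersed configurations).
All sampling goes through per-parameter inverse CDFs applied to a matrix of
uniforms, so a one-factor Gaussian copula (`latent_correlation`) can couple
parameters — real risk factors co-occur — while the default is independence,
which keeps marginal tests exact.

Event process: time to peri-implantitis is exponential with an annual rate
per overall risk category (a configurable Weibull shape, default 1, allows
non-constant-hazard sensitivity checks; the scale stays 1/rate). Default
rates are 0.006/patient-year for low and moderate and 0.006 × 4.782 for
high, so the true high vs pooled low/moderate hazard ratio equals the
reference estimate of 4.782. Censoring is administrative, uniform over the
3–14-year follow-up window (inclusion requires scores calculated at least
three years before the final examination; events themselves may occur
earlier than three years). For event patients one implant is rewritten to
meet the case definition so the patient-level flag and the implant-level
classifier agree; non-event implants stay below the probing-depth threshold.

What the generator does **not** model: joint distributions of the real
cohort (unpublished), within-patient correlation between implants,
time-varying risk profiles, or dependence of the hazard on individual
parameters beyond the overall category. Passing tests therefore demonstrate
correctness of the scoring and estimation machinery under a known truth, not
clinical performance on real data.

## Validation statistics

Kaplan–Meier, log-rank and Cox regression are computed with lifelines;
ROC/AUC with scikit-learn. Choices that matter:

- **Cox ties**: Efron's approximation (lifelines default), tolerant of the
  few ties a small cohort produces; the binary covariate is high-risk vs
  pooled low/moderate. CIs are Wald on the log scale, exp(β ± 1.96·se).
  Non-convergence and complete separation raise an explicit error rather
  than returning extreme estimates.
- **AUC for the 3-level score** is the Mann–Whitney probability with ties
  counted ½, identical to the trapezoidal area over the two interior
  thresholds; tests verify the equality against all-pairs enumeration.
- **2×2 reconstruction** from published summaries: true positives =
  sensitivity × events rounded half away from zero (with 13 events every
  printed sensitivity yields an unambiguous integer); any negative cell is an
  inconsistency error.
- **Cohen's kappa** is the standard unweighted form. On the reconstructed
  high-risk agreement table (16 both, 11 PRA-only, 4 IRA-only, 42 neither)
  it gives 0.534, not the 0.559 printed in the reference study; the printed
  value is not reproducible from the printed counts under the unweighted
  binary formula (it may have been computed on three ordered categories or
  with weighting). The discrepancy is asserted in the tests rather than
  reverse-engineered.
- Zero-denominator metrics raise a typed error; pipelines report those
  sections as unavailable instead of propagating NaN.
- p-values are two-sided; 0.05 is the significance label.

## Problem sizes in the acceptance checks

Quantities that depend on the unavailable patient-level data (the study's
own KM curves, HRs, AUCs) are replaced by parameter-recovery checks at
simulation scale chosen for stable Monte-Carlo error: Cox recovery uses 500
cohorts of n = 2000 (mean recovered HR within 10% of the true 4.8; the ~2%
upward drift of the mean HR is the expected Jensen bias of exponentiating an
unbiased log-hazard estimate), log-rank calibration uses 500 replicates of
n = 160 with a three-sigma binomial band around the nominal 0.05, and
marginal fidelity uses one cohort of n = 10,000 with a ±2-percentage-point
band.

## Known limitations

- The rule tables encode one specific adaptation of the IDRA; the original
  IDRA (which classifies most periodontitis-history populations high-risk)
  is out of scope.
- BL/age and implant bone level are consumed as pre-measured numbers;
  radiographic measurement and examiner calibration are out of scope.
- The deep-pocket count is a single patient-level count; whether implant
  sites contribute to it is left to the data producer.
- Percentages in reports are rounded to two decimals; reconstructed printed
  values are matched at their printed precision, which absorbs the reference
  tables' own mixed rounding/truncation.
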