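# Methods

`cardiomet` re-implements, as a tested pipeline, the cardiometabolic
phenotyping workflow used to compare hospitalized adults with Prader-Willi
syndrome (PWS) against age-, sex- and BMI-matched adults with essential
obesity (EOB): indirect calorimetry, bioimpedance body composition, derived
risk indices, five-criterion metabolic-syndrome (MetS) classification and
covariate-adjusted group comparison. Because the underlying subject-level
data are not public, the package includes a synthetic-cohort generator whose
defaults reproduce the published group summaries, so every stage is
exercisable and testable end to end.

## Physiology stage

**Energy expenditure.** Basal metabolic rate is computed from oxygen uptake
and carbon-dioxide output with the abbreviated Weir equation,
`EE = (3.941·VO2 + 1.106·VCO2) · 1440` kcal/day with gas rates in L/min.
The urinary-nitrogen term is omitted: the clinical protocol this models
collects no urine, and the protein correction is below 2% at ordinary
protein oxidation rates. Both caloric coefficients are overridable.

**Body composition.** Fat-free mass (FFM) is predicted from whole-body
resistance with sex-specific linear equations of the standard BIA form
`FFM = a + b·ht_cm²/R + c·weight + d·age` (a Gray-type equation for men, a
Bedogni-type equation for women in the modelled protocol). The package does
not hard-code any published population's coefficients — transcription errors
in such constants are silent and catastrophic — so the defaults are clearly
documented placeholders of plausible magnitude (F: b=0.60, c=0.20, d=−0.10;
M: b=0.65, c=0.26, d=−0.10; zero intercepts), and the supported path to
published equations is the sex-keyed `ffm_equations` block of the config
file. Heights are metres everywhere; the cm² conversion lives inside
`predict_ffm` so no silent 10⁴ factor can appear. Predictions are clamped
into (0, weight]. Fat mass is `weight − FFM` (mass conserved exactly);
percentage shares sum to 100 exactly.

**Normalisations.** BMR is reported absolute, per kg FFM and per kg body
weight. All derived quantities are computed per subject and then averaged
("mean of ratios"), matching how clinical tables behave; the package never
divides group means.

## Index stage

* **HOMA-IR** = insulin [µU/mL] × glucose [mmol/L] / 22.5.
* **VAI** (visceral adiposity index), sex-specific:
  men `(WC/(39.68+1.88·BMI))·(TG/1.03)·(1.31/HDL)`,
  women `(WC/(36.58+1.89·BMI))·(TG/0.81)·(1.52/HDL)`, TG and HDL in mmol/L —
  the constants are molar reference values, so the operation signature
  demands molar inputs and the pipeline converts explicitly.
* **MetS z-score**: sum of six SD-scaled deviations from sex-specific
  anchors (men HDL 40, TG 150, glucose 100, WC 94, SBP 130, DBP 85; women
  HDL 50 and WC 80, rest equal), with the HDL term reversed so higher HDL
  lowers risk. The score is identically zero at the anchor point for any SD
  scaling — a property the tests exploit. Two decisions are deliberately
  surfaced as configuration rather than silently fixed:
  1. *Which SDs?* The defining literature leaves the SD population
     unspecified. Default: sample SDs of the pooled analysis sample (all
     cohorts combined, recomputed per run), because cross-group score
     comparisons are only meaningful on a common scale. Per-cohort or
     externally supplied SD vectors are options.
  2. *Components.* Some descriptions of this score mention BMI z-score and
     systolic pressure only; the equations implemented here use WC and both
     pressures, as in the workflow being modelled. The printed equations
     win; the prose discrepancy is noted here.
* **Unit conversion**: precise molar factors by default (glucose 18.016,
  cholesterol fractions 38.67, TG 88.57 mg/dL per mmol/L). Rounded
  two-decimal factors (0.06/0.03/0.01), as printed in some clinical
  reports, are available as the `paper_rounded` preset; the rounded TG
  factor alone is an ~11% distortion, which is why it is a preset and not
  the default.

## MetS classification

Five component criteria — WC ≥ 102/88 cm (M/F), TG ≥ 150 mg/dL, HDL < 40/50
mg/dL (M/F), SBP ≥ 130 or DBP ≥ 85 mmHg, fasting glucose ≥ 100 mg/dL — each
also satisfied by the corresponding treatment/diagnosis flag (one lipid
treatment flag serves both TG and HDL; only a T2DM *diagnosis*, not
hypoglycaemic medication per se, trips the glucose criterion). Status is
MetS+ at ≥ 3 altered components. Boundary behaviour is inclusive ≥ for
WC/TG/BP/FPG and strict < for HDL, exactly as the criteria are stated.
The WC cut-offs are ATP-III-style values even though this rule set is often
labelled "IDF" (true IDF would make WC mandatory with lower cut-offs); the
thresholds dataclass is fully overridable so harmonised or IDF variants can
be configured. Prevalence percentages round half-up to integer percent
(14/32 → 44%).

## Statistical stage

`CohortComparison(data).fit()` follows the statsmodels Model→Results
pattern. Per variable:

* **Summaries**: mean with t-based 95% CI per group; percent difference
  `100·(comparison − reference)/reference` on group means (reference = EOB
  by convention in the shipped pipeline).
* **Routing**: Shapiro–Wilk on the residuals of the covariate-adjusted
  parametric fit; p < 0.05 sends the variable to the rank path. Normality of
  *residuals* (not raw y) is the defensible reading of "testing the data"
  when the model includes covariates; each routing decision is logged.
* **Two groups**: OLS of `y ~ 1 + group + age + sex`; the group coefficient
  is the adjusted mean difference and its two-sided t-test is the reported
  p-value. The rank path replaces y by mid-ranks and refits the same model
  (Conover-style rank-transform ANCOVA — "non-parametric ANCOVA" is
  under-specified in the clinical literature and this is the simplest
  defensible construction). A constant covariate (e.g. sex in a single-sex
  subset) is dropped with a logged warning rather than crashing the fit.
* **Four subgroups** (each cohort split by MetS status): same adjusted
  model with group dummies; omnibus F-test on the dummies; post-hoc
  pairwise tests are Tukey HSD on adjusted means (studentized-range p with
  k=4) when the variable passed normality, otherwise Bonferroni-corrected
  (×6) pairwise rank ANCOVAs. Significant pairs at α = 0.05 get shared
  letters. **Letter convention**: *identical* letters mark a *significant*
  difference — unusual, but it is the convention of the tables this
  pipeline renders, and every rendered legend says so.
* α = 0.05 throughout; no multiplicity correction across table rows (none
  is applied in the workflow being modelled). Sphericity corrections and
  repeated-measures machinery are out of scope: the design has no
  within-subject factor.

## Synthetic-cohort generator

The generator is first-class, tested code; its defaults *are* the study
conditions (n = 32 per cohort, 23 women / 9 men, variable means equal to
the published group means, SDs recovered from the printed 95% CIs via
`SD = half_width·√n / t_{0.975,n−1}`).

* **Law**: truncated multivariate normal. Only means and CIs are published;
  a Gaussian is the weakest model consistent with the parametric analysis
  the real data received. Default correlation structure (a modelling
  choice, the tables publish no covariances, overridable): weight–FFM–BMR
  block r = 0.8, glucose–insulin–HbA1c r = 0.5, lipid block r = 0.3, zero
  elsewhere — block-diagonal equicorrelation, hence positive semidefinite.
* **Truncation without bias**: subjects violating a lower bound (0 for
  concentrations, 18 y for age, 30 mmHg for pulse pressure) or a joint
  constraint (FFM < weight; invertible BIA equation) are redrawn, capped.
  Rejection alone would bias means upward — CRP's bound sits only 1.3 SD
  below its mean, a ~0.11 mg/dL bias against a 0.026 tolerance — so the
  pre-truncation mean of every bounded variable is solved numerically
  (Brent on the truncated-normal mean) to make the post-truncation marginal
  mean equal the target.
* **Blood pressure**: DBP and a positive pulse-pressure variable are
  generated; SBP = DBP + pulse pressure, guaranteeing SBP > DBP. The
  emitted pressures represent the protocol's already-averaged triplicate
  reading.
* **Back-solves**: VO2 is solved from the target BMR through the Weir
  identity at fixed RQ = 0.85 (VCO2 = 0.85·VO2), so calorimetry recovers
  the assigned BMR to numerical precision; resistance is solved from the
  target FFM through the configured sex-specific BIA equation, so body
  composition round-trips. Both let downstream stages be exercised with
  realistic inputs rather than pre-computed answers.
* **Sex structure**: sexes assigned by a seeded shuffle; additive sex
  offsets (default: height, men +0.10 m) are applied mean-preservingly
  (men +o·n_F/n, women −o·(n_M)/n) so cohort-level means stay on target
  while per-sex thresholds see both sexes at realistic values.
* **Flags**: 6/32 PWS and 4/32 EOB subjects carry a T2DM diagnosis (a
  seeded random subset), matching the modelled cohorts; treatment flags
  default to absent.
* **Determinism**: one integer seed per cohort spec; identical seeds give
  byte-identical cohorts.

What the generator does *not* emulate: genotype subtypes, hormone-therapy
subgroups, weight-history or longitudinal structure, skewness/heavy tails
in labs (real TG and CRP are right-skewed; here they are truncated
Gaussians), and any correlation structure beyond the three blocks. Passing
tests therefore demonstrate the *pipeline's* correctness and calibration
under the published first- and second-moment conditions — not distributional
realism of individual lab values.

## Numerical choices and degenerate inputs

* CI↔SD conversion uses the central Student-t quantile; zero-width CIs give
  SD 0 and the generator then produces point masses.
* `percent_difference` returns full precision; printed-table reproduction
  rounds half-up at one decimal (banker's rounding would turn 43.75% into
  44% vs 43.8%→43.8; clinical tables round half-up, e.g. 14/32 → 44%).
* OLS fits go through statsmodels; the test suite cross-checks coefficients
  against explicit normal-equations solutions.
* Tiny cohorts: the pipeline skips the four-subgroup post-hoc stage with a
  logged warning when any subgroup has fewer than 3 subjects; a constant
  covariate is dropped with a warning; constant samples are rejected by the
  normality screen and by SD estimation with explicit errors.
* Problem sizes used by the shipped checks (a deliberate scaling choice):
  parameter recovery at n = 5000 per cohort, estimator calibration at 2000
  simulated null datasets of n = 64, power/detection simulations at
  100–200 replicates.

## Known arithmetic inconsistencies in the published summaries

`verify_against_paper()` recomputes every printed headline percent
difference from the printed group means. Twelve reproduce exactly at
one-decimal rounding (body weight −20.9%, height −8.9%, FFM −23.5%, FM
−19.2%, BMR −25.5%, glucose +7.3%, HbA1c +7.9%, insulin −29.0%, total
cholesterol +9.6%, HDL +19.8%, and in the MetS subgroup tables FFM (MetS+)
−26.2% and BMR (MetS−) −27.2%). Several subgroup values do not
(e.g. MetS+ glucose printed +12.1 vs +13.8 from the table means; MetS− HDL
+18.9 vs +23.4; the within-PWS VAI value −58.6 matches only with the
reference group reversed), suggesting adjusted rather than raw means were
used for some rows. These are reported and flagged, never asserted. BMI
from group mean weight/height is shown as a sanity panel only: a ratio of
means is not the mean of per-subject ratios.
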