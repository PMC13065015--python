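# Methods

This package implements a register-based open-cohort analysis of prenatal
drinking-water PFAS exposure and childhood wheeze/asthma incidence, together
with a synthetic linked-register generator that reproduces the statistical
structure such an analysis assumes.  This note documents the models, the
defaults and why they were chosen, what the generator does and does not
emulate, and the numerical conventions.

## Study design being modelled

Children born over an 8-year window (default 2006-2013) in a county where a
subset of mothers drew drinking water from an AFFF-contaminated waterworks.
Each child is followed from birth on the **age time axis** until the first of:
outcome incidence, death, emigration, the outcome-specific age cap (3rd
birthday for wheeze, 12th for the asthma outcomes), or the administrative end
of study (default 2022-12-31).  Same-day ties resolve event > death >
emigration > age cap > administrative end, so incidence on a boundary still
counts.  Administrative censoring falls at the *end* of the closing day
(exit = date difference + 1), since registers record events through that day.

## Exposure proxy

Prenatal exposure is classified from the mother's registered address in the
five calendar years preceding the year of delivery: `very_high` if supplied
with contaminated water in all five years; `high` if in at least one but not
all; `intermediate` if resident in Ronneby but never on contaminated water;
`background` if never in Ronneby.  Window years with no record count as "not
in Ronneby" provided at least one window year is recorded; a fully
unrecorded window raises rather than silently defaulting to background, and
partially recorded windows are flagged in the output metadata.  Duplicate
records within a year merge by logical OR (exposure-maximising).  The same
rule with the window anchored at the serum sampling year classifies the
biomarker validation cohort.

## Outcome phenotyping

Declarative rules over ICD-10 diagnosis and ATC dispensation streams:

* **asthma** (through age 12): one asthma diagnosis (default prefix `J45`)
  OR two dispensations from the asthma medication set (default chapter
  `R03`), the repeat strictly later than the first and within
  `repeat_window_days` of it (default unlimited).  Incidence is dated by the
  first qualifying diagnosis or the *first* dispensation -- the repeat only
  confirms.  Both the first dispensation and its repeat must fall before the
  12th birthday (qualification happens within the observable window).
* **asthma (3+)**: asthma, plus at least one qualifying diagnosis or
  dispensation on or after the 3rd birthday (and before the 12th).  Incident
  age equals the asthma incident age (look-ahead confirmation).
* **wheeze** (0-36 months): a single diagnosis from {J45, J20-J22} or a
  single `R03` dispensation strictly before the 3rd birthday.

"36 months" and "age 12" are the calendar 3rd and 12th birthdays; events on
the birthday count as after it.  The exact Swedish medication code lists are
configurable rather than hard-coded: `R03` (obstructive-airway-disease
drugs) is the standard default, and wheeze shares the asthma medication set
unless configured otherwise.  The parental-asthma indicator applies the
asthma rule with no age cap to each parent's events within the study window
and ORs over the two parents.

## Synthetic register generator

The generator's role is to produce linked registers with *known ground
truth* so that every pipeline stage is testable without registry access.

* **Design margins.**  Group proportions default to 194/479/1,591/9,224 of
  11,488 (very high / high / intermediate / background); the default cohort
  size is 12,585 children so that the default missingness rates (6% smoking,
  2% education, 1.5% income) leave ~91% with complete covariates.  Covariate
  distributions are group-conditional with the observed margins (e.g.
  maternal smoking 9.8/17.1/8.3/7.2% across very-high/high/intermediate/
  background); covariates are drawn independently given the group, which is
  sufficient for confounding-adjustment testing but understates real
  covariate dependence.
* **Family structure.**  24% of children share a mother with one other
  cohort child.  Exposure group, education, income, foreign-born status and
  parental asthma are mother-level traits (shared by siblings); smoking,
  sex, parity and maternal age are drawn per delivery -- a simplification
  (sibling maternal ages are drawn independently).
* **Address histories** are constructed per mother to be exactly consistent
  with the assigned category for every child's window (contaminated in all
  years for very-high; only in each delivery-preceding year for high;
  Ronneby-uncontaminated for intermediate; non-Ronneby records for
  background), so the classifier round-trips 100% by construction.
* **Latent onsets.**  Outcome onset ages follow a piecewise-constant hazard
  on age with knots at 36 months and 6 years (relative levels 1.3/1.0/0.8
  for asthma; flat for the wheeze-specific component), multiplied by the
  group hazard ratio and exp(covariate effects).  The overall scale is
  solved numerically (Brent) so that the *expected phenotyped* cumulative
  incidence in the background group -- accounting for each child's own
  administrative horizon, death and emigration -- equals the configured
  target (defaults 0.17 asthma, 0.18 wheeze).  Strict asthma arises from
  asthma: onsets past 36 months qualify automatically; earlier onsets
  persist with probability 0.30, calibrated to the 17% vs 13% outcome mix.
* **Wheeze is deliberately a blend.**  Because J45/R03 events before 36
  months qualify for wheeze, an early asthma onset makes the child a wheeze
  case too; the configured wheeze hazard ratio applies only to the
  wheeze-specific component, so the realized phenotype-level wheeze effect
  is attenuated toward the asthma effect -- mirroring the lower specificity
  of a broad wheeze outcome in real registers.
* **Event emission.**  Latent cases emit streams that satisfy their
  algorithm exactly (diagnosis route with probability 0.3, otherwise first
  dispensation at onset plus a later repeat, plus a post-36-month event for
  persistent cases), confined to the observable window.  Latent non-cases
  optionally receive noise (isolated single dispensations or infant
  J20-J22 infections, rate 0.08), which can create wheeze false positives
  but never asthma ones.  With noise off, phenotyping recovers the latent
  labels and incident ages exactly -- the generator/phenotyper contract the
  test suite enforces.
* **True effect sizes** default to the adjusted hazard ratios the design
  targets (asthma: 0.95/0.96/1.44 for intermediate/high/very-high; wheeze
  component: 0.99/1.08/0.97); deaths (0.2%) and emigrations (3%) are uniform
  over the administrative window.  An optional mother-level lognormal shared
  frailty exists for sensitivity work and is **off by default**, since the
  design handles within-family correlation through cluster-robust variance
  rather than an outcome-model assumption.
* **Biomarkers.**  Serum PFOS/PFHxS/PFOA per exposure group are lognormal
  with medians and IQR spreads matching the validation-cohort calibration
  table (e.g. PFHxS median 164.8 ng/mL very-high vs 0.8 background), group
  sizes 80/54/39/36.

What passing tests on these data do **not** show: robustness to covariate
dependence beyond group-conditional independence, to informative censoring,
to time-varying exposure after birth, or to miscoded/duplicated register
rows -- none of which the generator emulates.

## Survival analysis

Cox proportional-hazards models are fitted by lifelines with **Efron tie
handling** (day-resolution ages make ties common); the model specification
is fixed by this package: age as the time axis, baseline hazard stratified
by sex (simple model) or sex x parity (adjusted model), exposure as three
indicator contrasts against background, and the adjusted confounder panel
(smoking; education as a 3-level factor; foreign-born parent; parental
asthma; income and maternal-age quartiles as 4-level factors, cutpoints
from the analysis cohort).  The simple model contains exposure only.

**Cluster-robust variance.**  The covariance used for all joint Wald tests
is a sandwich assembled in-package: score residuals of the partial
likelihood (Breslow hazard-increment form, supporting strata and left
truncation) are converted to delta-betas with the model covariance, summed
within maternal sibling clusters, and crossed.  On tie-free data this equals
the Wei-Lin robust estimator to machine precision (tested against
lifelines); with heavy ties it differs from an Efron-form sandwich only in
O(d/n) terms.  Reported per-coefficient CIs come from lifelines' own
cluster-robust standard errors.

**Proportional-hazards diagnostics.**  Per covariate: scaled Schoenfeld
residuals regressed on the Kaplan-Meier transform of time (lifelines).
Jointly for exposure: follow-up is episode-split on a 7-point event-time
quantile grid, exposure indicators are interacted with g(t) = 1 - KM(t)
evaluated at the *interval midpoint* -- the value must be constant within an
interval so that every subject at risk at an event time carries the same
covariate; evaluating at each episode's own stop instead biases the test
severely (rejection ~0.8 under the null in our checks, vs 0.05 when
interval-constant) -- and the three interaction coefficients are tested with
the cluster-robust Wald statistic.  The grid approximation affects power
only, not size; the test's 5% null calibration is exercised in the
acceptance suite.  The sex-modification analysis interacts exposure with
sex inside the sex-stratified model (the main effect is absorbed by the
baseline) and refits per sex.

## Multiple imputation

Missing covariates (smoking, education, income by default) are imputed with
chained equations via statsmodels `MICEData`, m = 20 datasets x 20
iterations by default (5 burn-in sweeps first).  Predictors always include
the outcome-specific event indicator and the Nelson-Aalen marginal
cumulative hazard at the child's own exit (plain d/n increments,
right-continuous), alongside complete covariates and exposure.  `MICEData`
imputes every variable by predictive mean matching, whose donors are
observed values -- binary and ordinal covariates therefore stay on their
support without needing per-type models; this library default was preferred
over per-variable logistic/ordinal imputers and is configurable upstream.
Income and age quartiles are re-derived within each completed dataset.
Per-dataset Cox fits are pooled on the log-HR scale by Rubin's rules
(T = W + (1 + 1/m)B, small-sample df), then exponentiated.

## Matched randomization inference

The potential-outcomes analysis contrasts very-high versus background
exposure on the complete-case cohort.  Distances are Rosenbaum's **robust
rank-based Mahalanobis**: pooled midranks per covariate, rank covariance
with its diagonal rescaled to the untied-rank variance (N^2 - 1)/12, ridge
regularisation (with a warning) if singular.  Matching is greedy 3:1
nearest-neighbour **without replacement**, treated units in input order,
distance ties broken by control input index -- deterministic; the ordering
choice is recorded in the output metadata since greedy results depend on it.
Balance is reported as standardized mean differences with the pre-matching
pooled SD as denominator for both columns.

The test statistic is the difference in Kaplan-Meier cumulative incidence
(treated minus control, percentage points) at the outcome horizon -- by
default the age cap (1,096 / 4,383 days); the KM step function is evaluated
at the last observed time at or before the horizon.  Under the Fisher sharp
null, one member of each matched set of four is uniformly relabelled as
treated per permutation (the unique scheme preserving the 1:3 design);
100,000 permutations by default, with the add-one estimate
p = (1 + #{T* >= T_obs}) / (1 + n_perm), so p is never 0 and the observed
assignment is always in the support.  With at most 8 sets the full 4^S
assignment space is enumerated instead and p is exact.  The one-sided
direction is excess incidence in the treated group.

## Validation statistics

Jonckheere-Terpstra: J sums between-group Mann-Whitney counts with half
credit for ties; inference uses the tie-corrected normal approximation
(no continuity correction), or exact enumeration of all assignments when
the total sample size is <= 10 (4-group enumeration grows multinomially, so
the threshold is deliberately small; both variants are exposed).
Sensitivity/specificity compare an algorithm against a configurable gold
standard -- the generator's latent labels on synthetic data, or e.g.
primary-care ascertainment on real data -- with NaN flags for empty classes.

## Numerical conventions and problem sizes

Dates are ISO-8601; ages are integer days; person-years divide by 365.25.
One root seed drives per-stage child seeds (independent `SeedSequence`
streams), so skipping a stage leaves the others bit-identical.  The
simulation studies shipped in the test suite use the sizes the package's
own validation design states: 200 seeds at n = 10,000 for hazard-ratio
recovery and CI coverage, 500 replicates for randomization-test null
calibration, 200 seeds at n = 600 for proportional-hazards test size, and
n = 16,000 cohorts for the matched-design structure check.

## Known limitations

Postnatal exposure, re-entry after emigration (children are censored
permanently at first emigration and flagged), competing risks (death is
censoring), frailty/time-varying-covariate models, and caliper or
propensity matching are out of scope.  The Breslow-form score residuals in
the sandwich are a slight approximation under heavy ties; the
episode-split grid bounds the resolution of the PH interaction test; exact
JT enumeration is limited to tiny samples.
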