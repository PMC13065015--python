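# pfascohort

Register-based open-cohort analysis of **prenatal drinking-water PFAS
exposure and childhood asthma/wheeze incidence**, built for epidemiologists
and biostatisticians who want the full analysis chain of an
address-proxy/registry design as tested, reusable code — and for anyone who
needs a synthetic linked-register testbed with known ground truth.

The setting it models: children born 2006–2013 in a county where roughly a
third of one municipality's households unknowingly drank water heavily
contaminated with PFAS from firefighting foam (AFFF).  Individual serum
measurements are unavailable for the birth cohort, so prenatal exposure is a
four-level proxy from the mother's address history, validated against a
serum biomarker cohort.

## What it implements

* **Synthetic linked registers** (`simulate`): births, annual maternal
  address snapshots with waterworks flags, ICD-10 diagnosis and ATC
  dispensation streams, vital events, parent events and serum biomarkers —
  with sibling clustering, group-shifted covariates, configurable true
  hazard ratios and a latent ground truth table.  Bit-reproducible from
  (config, seed).
* **Exposure proxy** (`exposure`): `very_high` / `high` / `intermediate` /
  `background` from the five calendar years of address history preceding
  delivery (or serum sampling).
* **Outcome phenotyping** (`phenotyping`): wheeze (0–36 months, single
  qualifying event), asthma (through age 12, diagnosis or repeat-confirmed
  dispensation, dated at the *first* dispensation), and strict asthma (3+)
  (additionally requires a qualifying event after 36 months); plus the
  parental-asthma indicator.
* **Open-cohort follow-up** (`cohort`): age-axis entry/exit with
  event > death > emigration > age-cap > administrative-end tie precedence,
  covariate panel with empirical quartiles, complete-case split with a
  missingness audit.
* **Survival models** (`survival`): Kaplan–Meier cumulative incidence; Cox
  models (Efron ties) with sex(-by-parity)-stratified baselines, exposure
  contrasts vs background, and an in-package sibling-cluster-robust
  sandwich covariance; Schoenfeld diagnostics and a joint
  exposure-by-time robust Wald test on episode-split data; sex-interaction
  analysis.
* **Multiple imputation** (`imputation`): MICE (statsmodels core) with the
  event indicator and Nelson–Aalen cumulative hazard at exit as mandatory
  predictors; Rubin's-rules pooling, T = W + (1 + 1/m)B.
* **Matched randomization inference** (`matching`): Rosenbaum's robust
  rank-based Mahalanobis distance, greedy 3:1 matching without replacement,
  SMD balance, and a one-sided Fisher sharp-null permutation test of the
  KM cumulative-incidence difference (exact enumeration for tiny designs).
* **Validation statistics** (`validation`): Jonckheere–Terpstra ordered
  trend test (tie-corrected z, exact for tiny n) and
  sensitivity/specificity against a gold standard.
* **Pipeline + CLI** (`report`, `cli`): one-command orchestration emitting
  tidy CSV tables (baseline characteristics, HR tables with events and
  person-years, pooled estimates, balance, KM curves, null distributions).

Register CSV schemas are documented in [docs/schema.md](docs/schema.md);
the modelling choices in [docs/methods.md](docs/methods.md).

## Worked example

Run the full pipeline on the default synthetic cohort (12,585 children,
~91% complete-case) with root seed 1:

```bash
pfascohort run --seed 1 --out-dir out/full
```

which logs the eight stages and prints the matched-analysis summary:

```
wheeze: KM difference +8.2 pp, one-sided p = 0.01375
asthma: KM difference +11.9 pp, one-sided p = 0.0007
asthma_3plus: KM difference +7.3 pp, one-sided p = 0.01442
```

`out/full/hr_table_asthma.csv` holds the hazard-ratio table (this seed):

| exposure | n | events | person-years | HR simple | HR adjusted (95% CI) |
|---|---|---|---|---|---|
| background | 9,154 | 1,611 (18%) | 92,892 | – | – |
| intermediate | 1,565 | 240 (15%) | 16,045 | 0.87 | 0.89 (0.78, 1.02) |
| high | 531 | 95 (18%) | 5,363 | 1.02 | 0.93 (0.75, 1.14) |
| very_high | 188 | 58 (31%) | 1,723 | 1.87 | 1.84 (1.42, 2.39) |

Reading these: the generator's default true very-high asthma hazard ratio
is 1.44, and a single cohort of this size estimates it with a log-scale
standard error of roughly 0.19, so seed-level estimates scatter widely
around the truth (the 200-seed recovery study in the test suite confirms
the estimator is centred).  The matched analysis reads as: after balancing
the eight confounders (all post-matching |SMD| ≤ 0.011 here, from
`covariate_balance.csv`), the KM cumulative incidence of asthma by age 12
was 11.9 percentage points higher among very-high-exposed children than
among their matched background controls, and under the sharp null a
difference at least that large arose in only ~0.07% of 100,000 within-set
exposure relabellings.  `biomarker_trend_tests.csv` shows the exposure-proxy
validation: serum PFHxS rises monotonically across the four categories
(Jonckheere–Terpstra z = 10.5, one-sided p ≈ 6e-26).

The same run is available as a library call:

```python
from pfascohort import SimConfig, PipelineOptions, run_pipeline
report = run_pipeline(SimConfig(seed=1), PipelineOptions())
print(report.matched_results["asthma"].t_obs)   # 11.93 (percentage points)
```

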