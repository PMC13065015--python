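# Register table schemas

All registers are plain CSV, one file per register, linked by person
identifiers.  `RegisterBundle.write_csv(dir)` / `read_csv(dir)` round-trip
them; `write_parquet` is available for large runs.  User-supplied data with
these columns can be fed to any downstream stage.

## persons.csv  (birth register)

| column | type | notes |
|---|---|---|
| `person_id` | str | child identifier, unique |
| `mother_id` | str | cluster identifier for sibling-robust variance |
| `father_id` | str | |
| `birth_date` | ISO-8601 date | within the configured birth-year range |
| `sex` | `F` / `M` | |
| `parity` | `primiparous` / `multiparous` | |
| `maternal_smoking` | 0/1, may be empty | early-pregnancy smoking |
| `maternal_education` | 0/1/2, may be empty | primary / upper secondary / post-secondary |
| `maternal_age_at_delivery` | years (float) | in (10, 60) |
| `foreign_born_parent` | 0/1 | at least one parent born abroad |
| `family_income` | float (1e5 SEK), may be empty | disposable income at delivery year |

## addresses.csv  (annual maternal address snapshots)

| column | type | notes |
|---|---|---|
| `person_id` | str | the **mother** |
| `calendar_year` | int | one row per mother-year |
| `in_ronneby` | bool | |
| `contaminated_water` | bool | implies `in_ronneby` |

## diagnoses.csv  (patient register)

| column | type | notes |
|---|---|---|
| `person_id` | str | child or parent |
| `event_date` | ISO-8601 date | >= birth date for children |
| `icd10_code` | str | prefix-matched (e.g. `J45`, `J21`) |
| `source` | `inpatient` / `outpatient` / `primary_care` | |

## dispensations.csv  (prescribed-drug register)

| column | type | notes |
|---|---|---|
| `person_id` | str | |
| `dispense_date` | ISO-8601 date | |
| `atc_code` | str | prefix-matched (e.g. `R03`) |

## vitals.csv

| column | type | notes |
|---|---|---|
| `person_id` | str | |
| `event_date` | ISO-8601 date | |
| `kind` | `death` / `emigration` | at most one death per person |

## latent.csv  (synthetic ground truth -- not part of a real linkage)

Per child: `exposure_group`, true (pre-missingness) covariate values,
`{outcome}_case` / `{outcome}_incident_day` for wheeze, asthma and
asthma_3plus, `death_day`, `emigration_day`, `admin_age_days`,
`cap3_days`, `cap12_days`.

## parents.csv  (synthetic ground truth)

`parent_id`, `role` (`mother`/`father`), `asthma_case` (0/1).

## biomarkers.csv

`person_id`, `exposure_group`, `sampling_year`, `pfos_ngml`, `pfhxs_ngml`,
`pfoa_ngml` (serum concentrations, ng/mL, all positive).
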