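"""One-call pipeline orchestration and emission of analysis tables.

``run_pipeline`` executes the full analysis chain on a synthetic register
bundle: simulate -> classify exposure -> phenotype outcomes -> build
open-cohort follow-up -> Kaplan-Meier + Cox models -> MICE/Rubin pooling ->
matched randomization inference -> validation statistics, all governed by a
single root seed (per-stage child seeds keep stages reproducible when some
are skipped).  The resulting ``ReportBundle`` holds tidy tables mirroring a
register-study results section: baseline characteristics, hazard-ratio
tables with events and person-years, pooled-imputation estimates, matched
analysis results, KM curve data, covariate balance, and outcome-overlap
counts.
"""

from __future__ import annotations

import dataclasses
import hashlib
import logging
import math
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import __version__
from .simulate import (
    SimConfig, RegisterBundle, generate_bundle, generate_biomarker_cohort,
    GROUP_LABELS, BIOMARKER_CALIBRATION,
)
from .exposure import classify_cohort
from .phenotyping import (
    CodeSetConfig, OUTCOMES, ascertain_cohort, parental_asthma_cohort,
)
from .cohort import (
    COVARIATE_COLUMNS, build_followup_cohort, derive_covariates, complete_case_split,
)
from .survival import (
    EXPOSURE_DUMMIES, add_exposure_dummies, cox_fit, km_curve, ph_diagnostics,
    interaction_wald, DAYS_PER_YEAR,
)
from .imputation import nelson_aalen_at_exit, run_chained_imputation, pool_cox_fits
from .matching import (
    match_cohort, covariate_balance, fisher_randomization_test,
)
from .validation import jonckheere_terpstra, confusion_metrics

logger = logging.getLogger("pfascohort")

ADJUSTED_COVARIATES = [
    "smoking", "education", "foreign_born_parent", "parental_asthma",
    "income_quartile", "maternal_age_quartile",
]
HORIZON_DAYS = {"wheeze": 1096.0, "asthma": 4383.0, "asthma_3plus": 4383.0}
EXPOSURE_ORDER = ("background", "intermediate", "high", "very_high")


def percent(numerator: float, denominator: float) -> int:
    """Whole-number percentage as printed in cohort tables (half rounds up)."""
    if denominator == 0:
        raise ZeroDivisionError("empty denominator")
    return int(math.floor(100.0 * numerator / denominator + 0.5))


def pp_difference(a: float, b: float, decimals: int = 1) -> float:
    """Difference of two percentages, in percentage points, to table precision."""
    return round(a - b, decimals)


@dataclasses.dataclass
class PipelineOptions:
    n_perm: int = 100_000
    mice_m: int = 20
    mice_iterations: int = 20
    skip_imputation: bool = False
    skip_matching: bool = False
    outcomes: tuple = OUTCOMES
    codes: CodeSetConfig = dataclasses.field(default_factory=CodeSetConfig)


@dataclasses.dataclass
class ReportBundle:
    baseline_table: pd.DataFrame
    hr_tables: dict
    pooled_tables: dict
    matched_results: dict
    balance_table: Optional[pd.DataFrame]
    km_data: dict
    outcome_overlap: pd.DataFrame
    ph_tests: dict
    sex_interaction: dict
    trend_tests: pd.DataFrame
    confusion: pd.DataFrame
    missingness_report: pd.DataFrame
    metadata: dict

    def write(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.baseline_table.to_csv(out / "baseline_characteristics.csv", index=False)
        for outcome, tab in self.hr_tables.items():
            tab.to_csv(out / f"hr_table_{outcome}.csv", index=False)
        for outcome, tab in self.pooled_tables.items():
            tab.to_csv(out / f"pooled_hr_{outcome}.csv", index=False)
        for outcome, km in self.km_data.items():
            km.to_csv(out / f"km_curves_{outcome}.csv", index=False)
        if self.balance_table is not None:
            self.balance_table.to_csv(out / "covariate_balance.csv", index=False)
        self.outcome_overlap.to_csv(out / "outcome_overlap.csv", index=False)
        self.trend_tests.to_csv(out / "biomarker_trend_tests.csv", index=False)
        self.confusion.to_csv(out / "phenotyping_accuracy.csv", index=False)
        self.missingness_report.to_csv(out / "missingness_report.csv", index=False)
        if self.matched_results:
            rows = [
                {
                    "outcome": o, "t_obs_pp": r.t_obs, "one_sided_p": r.p_value,
                    "n_perm": r.n_perm, "exact": r.exact,
                    "null_mean": r.null_mean, "null_sd": r.null_sd,
                }
                for o, r in self.matched_results.items()
            ]
            pd.DataFrame(rows).to_csv(out / "matched_randomization.csv", index=False)
            for o, r in self.matched_results.items():
                if r.null_histogram is not None:
                    r.null_histogram.to_csv(out / f"null_distribution_{o}.csv", index=False)
        pd.Series(self.metadata).to_json(out / "run_metadata.json", indent=2)


def _stage_seed(root_seed: int, stage: int) -> int:
    return int(np.random.SeedSequence((int(root_seed), 1000 + stage)).generate_state(1)[0] % (2**31))


def _baseline_table(cov: pd.DataFrame, exposure: pd.Series) -> pd.DataFrame:
    """Cohort characteristics, overall and per exposure group."""
    groups = {"overall": cov}
    for g in EXPOSURE_ORDER:
        groups[g] = cov[exposure == g]
    rows = []

    def n_pct(name, indicator):
        row = {"variable": name}
        for label, sub in groups.items():
            k = int(indicator(sub).sum())
            row[label] = f"{k} ({percent(k, len(sub))}%)" if len(sub) else "0"
        rows.append(row)

    def med_iqr(name, col):
        row = {"variable": name}
        for label, sub in groups.items():
            if len(sub):
                q1, q2, q3 = sub[col].quantile([0.25, 0.5, 0.75])
                row[label] = f"{q2:.1f} [{q1:.1f}, {q3:.1f}]"
            else:
                row[label] = ""
        rows.append(row)

    rows.append({"variable": "N", **{lbl: len(sub) for lbl, sub in groups.items()}})
    n_pct("Maternal smoking in early pregnancy (yes)", lambda s: s["smoking"] == 1)
    n_pct("Parity (multiparous)", lambda s: s["parity"] == 1)
    n_pct("Sex (female)", lambda s: s["sex"] == 1)
    n_pct("Maternal education: primary/lower secondary", lambda s: s["education"] == 0)
    n_pct("Maternal education: upper secondary", lambda s: s["education"] == 1)
    n_pct("Maternal education: post secondary", lambda s: s["education"] == 2)
    med_iqr("Maternal age at delivery", "maternal_age")
    n_pct("At least one foreign-born parent", lambda s: s["foreign_born_parent"] == 1)
    med_iqr("Family disposable income (1e5 SEK)", "family_income")
    n_pct("Parental asthma (yes)", lambda s: s["parental_asthma"] == 1)
    return pd.DataFrame(rows)


def _hr_table(fu: pd.DataFrame, simple, adjusted) -> pd.DataFrame:
    rows = []
    for g in EXPOSURE_ORDER:
        sub = fu[fu["exposure"] == g]
        events = int(sub["event"].sum())
        py = float(sub["exit_age_days"].sum()) / DAYS_PER_YEAR
        row = {
            "exposure": g,
            "n": len(sub),
            "events": events,
            "events_pct": percent(events, len(sub)) if len(sub) else np.nan,
            "person_years": round(py, 0),
        }
        if g == "background":
            row.update({"hr_simple": 1.0, "hr_adjusted": 1.0})
        else:
            name = f"exp_{g}"
            for label, res in (("simple", simple), ("adjusted", adjusted)):
                s = res.summary.loc[name]
                row[f"hr_{label}"] = s["hr"]
                row[f"hr_{label}_ci_low"] = s["hr_ci_low"]
                row[f"hr_{label}_ci_high"] = s["hr_ci_high"]
        rows.append(row)
    return pd.DataFrame(rows)


def _outcome_overlap(asc: pd.DataFrame) -> pd.DataFrame:
    wide = asc.pivot(index="person_id", columns="outcome", values="is_case").astype(bool)
    any_case = wide.any(axis=1)
    combos = (
        wide[any_case]
        .groupby(list(wide.columns))
        .size()
        .reset_index(name="n_children")
    )
    combos.attrs["n_any_outcome"] = int(any_case.sum())
    return combos


def run_pipeline(
    config: Optional[SimConfig] = None,
    options: Optional[PipelineOptions] = None,
    out_dir=None,
) -> ReportBundle:
    """Execute the full synthetic-register analysis pipeline."""
    config = config or SimConfig()
    options = options or PipelineOptions()

    logger.info("stage 1/8: simulating registers (n=%d, seed=%d)", config.n_children, config.seed)
    bundle = generate_bundle(config)
    biomarkers = generate_biomarker_cohort(config)
    persons = bundle.persons
    if persons.empty:
        raise ValueError("pipeline requires a non-empty cohort")

    logger.info("stage 2/8: exposure classification")
    exposure_df = classify_cohort(bundle.addresses, persons)

    logger.info("stage 3/8: outcome phenotyping")
    asc = ascertain_cohort(bundle.diagnoses, bundle.dispensations, persons, options.codes)
    parental = parental_asthma_cohort(
        persons, bundle.diagnoses, bundle.dispensations, options.codes,
        study_window=("2006-01-01", config.admin_end),
    )

    logger.info("stage 4/8: covariates and complete-case split")
    cov = derive_covariates(persons, parental)
    cov = cov.merge(exposure_df[["person_id", "exposure"]], on="person_id")
    complete_cov, missingness = complete_case_split(cov)

    hr_tables, km_data, ph_tests, sex_tests, pooled_tables = {}, {}, {}, {}, {}
    matched_results: dict = {}
    balance_df = None
    followups_complete = {}

    for outcome in options.outcomes:
        logger.info("stage 5/8: survival analysis for %s", outcome)
        fu = build_followup_cohort(persons, asc, bundle.vitals, config.admin_end, outcome)
        fu_cov = fu.merge(cov, on="person_id")
        fu_cov = add_exposure_dummies(fu_cov)
        fu_cc = fu_cov[fu_cov["person_id"].isin(complete_cov["person_id"])].reset_index(drop=True)
        followups_complete[outcome] = fu_cc

        curves = km_curve(fu_cc, group_col="exposure")
        km_data[outcome] = pd.concat(
            [c.table.assign(exposure=g) for g, c in curves.items()], ignore_index=True
        )
        simple = cox_fit(fu_cc, covariates=(), strata=("sex",))
        adjusted = cox_fit(fu_cc, covariates=ADJUSTED_COVARIATES, strata=("sex", "parity"))
        hr_tables[outcome] = _hr_table(fu_cc, simple, adjusted)
        try:
            schoenfeld, joint = ph_diagnostics(adjusted, fu_cc, covariates=ADJUSTED_COVARIATES)
            ph_tests[outcome] = {"schoenfeld": schoenfeld, "joint_exposure_time": joint}
        except ValueError as err:
            ph_tests[outcome] = {"undefined": str(err)}
        joint_sex, per_sex = interaction_wald(fu_cc, covariates=ADJUSTED_COVARIATES)
        sex_tests[outcome] = {
            "joint_p": joint_sex.p_value,
            "stratified_hr_very_high": {
                lvl: float(res.summary.loc["exp_very_high", "hr"]) for lvl, res in per_sex.items()
            },
        }

        if not options.skip_imputation:
            logger.info("stage 6/8: multiple imputation for %s", outcome)
            imp = fu_cov.merge(nelson_aalen_at_exit(fu_cov).rename("nelson_aalen"),
                               left_index=True, right_index=True)
            stack = run_chained_imputation(
                imp,
                impute_cols=["smoking", "education", "family_income"],
                predictor_cols=["event", "nelson_aalen", "sex", "parity",
                                "foreign_born_parent", "parental_asthma",
                                "maternal_age", *EXPOSURE_DUMMIES],
                m=options.mice_m,
                iterations=options.mice_iterations,
                seed=_stage_seed(config.seed, 6),
            )

            def _fit_completed(d: pd.DataFrame):
                d = d.copy()
                d["income_quartile"] = pd.qcut(d["family_income"], 4, labels=False, duplicates="drop") + 1.0
                d["maternal_age_quartile"] = pd.qcut(d["maternal_age"], 4, labels=False, duplicates="drop") + 1.0
                return cox_fit(d, covariates=ADJUSTED_COVARIATES, strata=("sex", "parity"))

            pooled_tables[outcome] = pool_cox_fits(stack, _fit_completed, param_names=EXPOSURE_DUMMIES)

    if not options.skip_matching:
        logger.info("stage 7/8: matched randomization inference")
        treated = complete_cov[complete_cov["exposure"] == "very_high"].reset_index(drop=True)
        controls = complete_cov[complete_cov["exposure"] == "background"].reset_index(drop=True)
        if len(controls) >= 3 * len(treated) and len(treated) > 0:
            sets = match_cohort(treated, controls, COVARIATE_COLUMNS)
            matched_ids = {cid for s in sets for cid in s.control_ids}
            matched_controls = controls[controls["person_id"].isin(matched_ids)]
            balance = covariate_balance(treated, controls, matched_controls, COVARIATE_COLUMNS)
            balance_df = pd.DataFrame([dataclasses.asdict(b) for b in balance])
            for outcome in options.outcomes:
                fu_cc = followups_complete[outcome]
                matched_results[outcome] = fisher_randomization_test(
                    sets, fu_cc, horizon=HORIZON_DAYS[outcome],
                    n_perm=options.n_perm, seed=_stage_seed(config.seed, 7),
                    outcome=outcome,
                )
        else:
            logger.warning("matching skipped: insufficient background controls")

    logger.info("stage 8/8: validation statistics")
    trend_rows = []
    for analyte in BIOMARKER_CALIBRATION:
        grouped = [
            biomarkers.loc[biomarkers["exposure_group"] == g, analyte].to_numpy()
            for g in EXPOSURE_ORDER
        ]
        res = jonckheere_terpstra([g for g in grouped if len(g)])
        trend_rows.append({
            "analyte": analyte, "J": res.statistic, "z": res.z,
            "one_sided_p": res.p_value, "exact": res.exact, "n": res.n,
        })
    trend_tests = pd.DataFrame(trend_rows)

    conf_rows = []
    latent = bundle.latent.set_index("person_id")
    for outcome in options.outcomes:
        pred = (
            asc[asc["outcome"] == outcome]
            .set_index("person_id")["is_case"]
            .reindex(latent.index)
            .fillna(False)
        )
        gold = latent[f"{outcome}_case"].astype(bool)
        sens, spec, table = confusion_metrics(pred.to_numpy(dtype=bool), gold.to_numpy())
        conf_rows.append({
            "outcome": outcome, "sensitivity": sens, "specificity": spec,
            "tp": table.tp, "fp": table.fp, "tn": table.tn, "fn": table.fn,
        })
    confusion = pd.DataFrame(conf_rows)

    overlap = _outcome_overlap(asc)
    baseline = _baseline_table(
        complete_cov, complete_cov["exposure"]
    )

    metadata = {
        "package_version": __version__,
        "seed": config.seed,
        "config_sha256": hashlib.sha256(config.to_json().encode()).hexdigest(),
        "n_children": int(len(persons)),
        "n_complete_case": int(len(complete_cov)),
        "retained_fraction": float(missingness.attrs["retained_fraction"]),
        "n_perm": options.n_perm,
        "skip_imputation": options.skip_imputation,
    }

    report = ReportBundle(
        baseline_table=baseline,
        hr_tables=hr_tables,
        pooled_tables=pooled_tables,
        matched_results=matched_results,
        balance_table=balance_df,
        km_data=km_data,
        outcome_overlap=overlap,
        ph_tests=ph_tests,
        sex_interaction=sex_tests,
        trend_tests=trend_tests,
        confusion=confusion,
        missingness_report=missingness,
        metadata=metadata,
    )
    if out_dir is not None:
        report.write(out_dir)
    return report
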