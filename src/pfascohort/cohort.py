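"""Open-cohort follow-up construction and analysis covariates.

Children enter at birth and are followed on the age time axis until the
earliest of outcome incidence, death, emigration, the outcome-specific age
cap (3rd birthday for wheeze, 12th for the asthma variants), or the
administrative end of study.  Ties on the same day resolve in the order
event > death > emigration > age cap > administrative end, so incidence on a
censoring boundary still counts as an event.

The analysis covariate panel codes the confounders the way the survival
models consume them: binaries as 0/1, education as a 3-level ordinal, family
income and maternal age as cohort-empirical quartiles, and the
parental-asthma indicator from the phenotyping engine.  Siblings share their
mother's id as the cluster identifier.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .phenotyping import OutcomeAscertainment, age_cap_days

__all__ = [
    "FollowUpRecord",
    "CENSOR_PRECEDENCE",
    "OUTCOME_CAP_YEARS",
    "build_followup",
    "build_followup_cohort",
    "derive_covariates",
    "complete_case_split",
    "COVARIATE_COLUMNS",
]

CENSOR_PRECEDENCE = ("event", "death", "emigration", "age_cap", "admin_end")
OUTCOME_CAP_YEARS = {"wheeze": 3, "asthma": 12, "asthma_3plus": 12}

COVARIATE_COLUMNS = [
    "smoking", "education", "foreign_born_parent", "parental_asthma",
    "income_quartile", "maternal_age_quartile", "sex", "parity",
]


class FollowUpError(ValueError):
    """No positive follow-up time can be constructed."""


@dataclasses.dataclass(frozen=True)
class FollowUpRecord:
    person_id: str
    cluster_id: str
    outcome: str
    entry_age_days: int
    exit_age_days: int
    event: bool
    censor_reason: str

    def __post_init__(self):
        if self.exit_age_days <= 0:
            raise FollowUpError("exit_age_days must be positive")
        if self.event and self.censor_reason != "event":
            raise ValueError("event implies censor_reason == 'event'")


def build_followup(
    child,
    ascertainment: OutcomeAscertainment,
    vitals,
    admin_end,
    outcome_cap_years: Optional[int] = None,
) -> FollowUpRecord:
    """Follow-up record for one child and one outcome.

    ``child`` needs ``person_id``, ``mother_id`` and ``birth_date`` fields
    (mapping or object); ``vitals`` is that child's death/emigration events.
    """
    get = child.get if isinstance(child, dict) else lambda k: getattr(child, k)
    birth = pd.Timestamp(get("birth_date"))
    cap_years = outcome_cap_years or OUTCOME_CAP_YEARS[ascertainment.outcome]
    cap_days = age_cap_days(birth, cap_years)
    # registers cover events through the closing date inclusive, so the
    # administrative exit is one day past the date difference
    admin_days = (pd.Timestamp(admin_end) - birth).days + 1

    death_days = emig_days = np.inf
    for v in vitals or []:
        vget = v.get if isinstance(v, dict) else lambda k, v=v: getattr(v, k)
        day = (pd.Timestamp(vget("event_date")) - birth).days
        if vget("kind") == "death":
            death_days = min(death_days, day)
        elif vget("kind") == "emigration":
            emig_days = min(emig_days, day)

    incident = ascertainment.incident_age_days if ascertainment.is_case else np.inf
    candidates = [incident, death_days, emig_days, cap_days, admin_days]
    exit_days = min(candidates)
    if exit_days <= 0:
        raise FollowUpError(f"nonpositive follow-up for {get('person_id')}")
    reason = CENSOR_PRECEDENCE[int(np.argmin(candidates))]
    return FollowUpRecord(
        person_id=get("person_id"),
        cluster_id=get("mother_id"),
        outcome=ascertainment.outcome,
        entry_age_days=0,
        exit_age_days=int(exit_days),
        event=reason == "event",
        censor_reason=reason,
    )


def build_followup_cohort(
    persons: pd.DataFrame,
    ascertainments: pd.DataFrame,
    vitals: pd.DataFrame,
    admin_end,
    outcome: str,
) -> pd.DataFrame:
    """Vectorised follow-up table for one outcome over the whole cohort.

    ``ascertainments`` is the long output of ``phenotyping.ascertain_cohort``.
    Children censored at a first emigration never re-enter; such records are
    flagged via ``censor_reason == 'emigration'``.
    """
    asc = ascertainments[ascertainments["outcome"] == outcome].set_index("person_id")
    asc = asc.reindex(persons["person_id"])
    birth = pd.to_datetime(persons["birth_date"])
    cap_days = ((birth + pd.DateOffset(years=OUTCOME_CAP_YEARS[outcome])) - birth).dt.days.to_numpy()
    admin_days = (pd.Timestamp(admin_end) - birth).dt.days.to_numpy() + 1

    death = np.full(len(persons), np.inf)
    emig = np.full(len(persons), np.inf)
    if vitals is not None and len(vitals):
        v = vitals.merge(persons[["person_id", "birth_date"]], on="person_id")
        v["day"] = (pd.to_datetime(v["event_date"]) - pd.to_datetime(v["birth_date"])).dt.days
        pos = pd.Index(persons["person_id"])
        for kind, arr in (("death", death), ("emigration", emig)):
            sub = v[v["kind"] == kind].groupby("person_id")["day"].min()
            arr[pos.get_indexer(sub.index)] = sub.to_numpy()

    incident = np.where(
        asc["is_case"].fillna(False).to_numpy(dtype=bool),
        asc["incident_age_days"].to_numpy(dtype=float),
        np.inf,
    )
    candidates = np.column_stack([incident, death, emig, cap_days, admin_days])
    which = np.argmin(candidates, axis=1)  # ties resolve by column order
    exit_days = candidates[np.arange(len(persons)), which]
    if (exit_days <= 0).any():
        bad = persons["person_id"].to_numpy()[exit_days <= 0][:5]
        raise FollowUpError(f"nonpositive follow-up for {list(bad)}")
    return pd.DataFrame({
        "person_id": persons["person_id"].to_numpy(),
        "cluster_id": persons["mother_id"].to_numpy(),
        "outcome": outcome,
        "entry_age_days": 0,
        "exit_age_days": exit_days.astype(int),
        "event": (which == 0).astype(int),
        "censor_reason": np.array(CENSOR_PRECEDENCE)[which],
    })


def derive_covariates(
    persons: pd.DataFrame,
    parental_asthma: pd.Series,
    n_quantiles: int = 4,
) -> pd.DataFrame:
    """Analysis covariate panel, one row per child.

    Income and maternal-age quartile cutpoints are the empirical quartiles of
    the analysis cohort itself.  Missing values propagate (quartile = NaN) so
    the complete-case split can act on them.
    """
    out = pd.DataFrame({"person_id": persons["person_id"].to_numpy()})
    out["smoking"] = persons["maternal_smoking"].to_numpy(dtype=float)
    out["education"] = persons["maternal_education"].to_numpy(dtype=float)
    out["foreign_born_parent"] = persons["foreign_born_parent"].to_numpy(dtype=float)
    out["parental_asthma"] = (
        parental_asthma.reindex(persons["person_id"]).to_numpy(dtype=float)
    )
    out["sex"] = (persons["sex"].to_numpy() == "F").astype(float)
    out["parity"] = (persons["parity"].to_numpy() == "multiparous").astype(float)
    out["maternal_age"] = persons["maternal_age_at_delivery"].to_numpy(dtype=float)
    out["family_income"] = persons["family_income"].to_numpy(dtype=float)

    for raw, col in (("family_income", "income_quartile"),
                     ("maternal_age", "maternal_age_quartile")):
        values = out[raw]
        if values.dropna().nunique() < n_quantiles:
            warnings.warn(f"{raw} is (near-)degenerate; emitting a single level")
            out[col] = np.where(values.notna(), 1.0, np.nan)
        else:
            out[col] = pd.qcut(values, n_quantiles, labels=False, duplicates="drop") + 1.0
    return out


def complete_case_split(
    cohort: pd.DataFrame,
    covariate_cols: Sequence[str] = tuple(COVARIATE_COLUMNS),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split into the complete-covariate subcohort and a missingness report.

    The report lists, per covariate, the number and share of missing values,
    and compares the mean of every covariate between included and excluded
    children (the usual completeness-bias audit table).
    """
    cols = [c for c in covariate_cols if c in cohort.columns]
    missing_any = cohort[cols].isna().any(axis=1)
    complete = cohort[~missing_any].copy()
    if complete.empty:
        raise FollowUpError("no children with complete covariate information")

    rows = []
    for c in cols:
        n_missing = int(cohort[c].isna().sum())
        rows.append({
            "covariate": c,
            "n_missing": n_missing,
            "pct_missing": 100.0 * n_missing / len(cohort),
            "mean_included": float(cohort.loc[~missing_any, c].mean()),
            "mean_excluded": float(cohort.loc[missing_any, c].mean()) if missing_any.any() else np.nan,
        })
    report = pd.DataFrame(rows)
    report.attrs["n_total"] = len(cohort)
    report.attrs["n_complete"] = len(complete)
    report.attrs["retained_fraction"] = len(complete) / len(cohort)
    return complete, report
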