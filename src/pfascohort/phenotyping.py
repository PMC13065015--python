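"""Register-based outcome phenotyping for childhood wheeze and asthma.

Three outcomes are ascertained from specialist-care diagnoses (ICD-10) and
pharmacy dispensations (ATC):

``asthma``
    Through age 12.  A child is a case if it has at least one asthma
    diagnosis (default J45) before the 12th birthday, or at least two asthma
    medication dispensations (default ATC chapter R03) before the 12th
    birthday, the second within ``repeat_window_days`` of the first
    (unlimited by default).  The incidence date is the first qualifying
    diagnosis or the *first* dispensation -- the repeat only confirms.

``asthma_3plus``
    The stricter variant reflecting separate diagnostic guidelines for
    children under/over 36 months: asthma criteria plus at least one
    qualifying diagnosis or dispensation on or after the 3rd birthday.
    The incidence date is the same as for ``asthma`` (lookahead
    confirmation).

``wheeze``
    Ages 0-36 months.  A single diagnosis of asthma or acute lower
    respiratory infection (default J45, J20-J22) or a single dispensation
    from the wheeze medication set (default R03), strictly before the 3rd
    birthday.

Boundary convention: "36 months" and "age 12" are the 3rd and 12th
birthdays; events falling exactly on the birthday count as *after* it.

The same rule engine with no age cap gives the parental-asthma indicator.
"""

from __future__ import annotations

import dataclasses
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CodeSetConfig",
    "OutcomeAscertainment",
    "OUTCOMES",
    "age_cap_days",
    "ascertain_asthma",
    "ascertain_asthma_3plus",
    "ascertain_wheeze",
    "ascertain_parental_asthma",
    "ascertain_cohort",
    "parental_asthma_cohort",
]

OUTCOMES = ("wheeze", "asthma", "asthma_3plus")


class EventBeforeBirthError(ValueError):
    """A diagnosis or dispensation predates the child's birth."""


@dataclasses.dataclass(frozen=True)
class CodeSetConfig:
    """Configurable ICD-10 / ATC prefix sets defining the outcome algorithms."""

    asthma_icd: tuple[str, ...] = ("J45",)
    wheeze_icd: tuple[str, ...] = ("J45", "J20", "J21", "J22")
    asthma_atc: tuple[str, ...] = ("R03",)
    wheeze_atc: tuple[str, ...] = ("R03",)
    repeat_window_days: Optional[int] = None  # None = unlimited

    def __post_init__(self):
        for name in ("asthma_icd", "wheeze_icd", "asthma_atc", "wheeze_atc"):
            if not getattr(self, name):
                raise ValueError(f"{name} must be a nonempty code set")
        if self.repeat_window_days is not None and self.repeat_window_days <= 0:
            raise ValueError("repeat_window_days must be positive or None")


@dataclasses.dataclass(frozen=True)
class OutcomeAscertainment:
    outcome: str
    is_case: bool
    incident_age_days: Optional[int] = None

    def __post_init__(self):
        if self.is_case != (self.incident_age_days is not None):
            raise ValueError("incident_age_days must be present iff is_case")
        if self.incident_age_days is not None and self.incident_age_days < 0:
            raise ValueError("incident_age_days must be nonnegative")


def age_cap_days(birth_date, years: int) -> int:
    """Days from birth to the ``years``-th birthday (calendar-exact)."""
    birth = pd.Timestamp(birth_date)
    return int((birth + pd.DateOffset(years=years) - birth).days)


def _event_ages(events, date_col: str, code_col: str, birth_date, prefixes) -> np.ndarray:
    """Sorted ages (days) of events whose code matches any prefix."""
    if events is None or len(events) == 0:
        return np.empty(0, dtype=int)
    if isinstance(events, pd.DataFrame):
        dates = pd.to_datetime(events[date_col])
        codes = events[code_col].astype(str)
    else:
        recs = [
            (rec[date_col], rec[code_col]) if isinstance(rec, dict)
            else (getattr(rec, date_col), getattr(rec, code_col))
            for rec in events
        ]
        dates = pd.to_datetime([r[0] for r in recs])
        codes = pd.Series([str(r[1]) for r in recs])
    ages = np.asarray((pd.DatetimeIndex(dates) - pd.Timestamp(birth_date)).days)
    if len(ages) and ages.min() < 0:
        raise EventBeforeBirthError("event dated before birth")
    keep = codes.str.startswith(tuple(prefixes)).to_numpy()
    return np.sort(ages[keep])


def _first_repeat_qualified(rx_ages: np.ndarray, window: Optional[int]) -> Optional[int]:
    """Earliest dispensation with a strictly later repeat within ``window`` days."""
    for i, a in enumerate(rx_ages):
        later = rx_ages[i + 1:]
        later = later[later > a]
        if window is not None:
            later = later[later <= a + window]
        if later.size:
            return int(a)
    return None


def _asthma_incident(dx, rx, birth_date, codes: CodeSetConfig, cap_days: Optional[int]):
    """Incident age under the asthma rule, or None; also the qualifying ages."""
    dx_ages = _event_ages(dx, "event_date", "icd10_code", birth_date, codes.asthma_icd)
    rx_ages = _event_ages(rx, "dispense_date", "atc_code", birth_date, codes.asthma_atc)
    if cap_days is not None:
        dx_ages = dx_ages[dx_ages < cap_days]
        rx_ages = rx_ages[rx_ages < cap_days]
    candidates = []
    if dx_ages.size:
        candidates.append(int(dx_ages[0]))
    rx_first = _first_repeat_qualified(rx_ages, codes.repeat_window_days)
    if rx_first is not None:
        candidates.append(rx_first)
    incident = min(candidates) if candidates else None
    return incident, dx_ages, rx_ages


def ascertain_asthma(dx, rx, birth_date, codes: CodeSetConfig = CodeSetConfig()) -> OutcomeAscertainment:
    """Asthma through age 12: one diagnosis OR a repeat-confirmed dispensation."""
    cap = age_cap_days(birth_date, 12)
    incident, _, _ = _asthma_incident(dx, rx, birth_date, codes, cap)
    return OutcomeAscertainment("asthma", incident is not None, incident)


def ascertain_asthma_3plus(dx, rx, birth_date, codes: CodeSetConfig = CodeSetConfig()) -> OutcomeAscertainment:
    """Asthma plus at least one qualifying event on/after the 3rd birthday."""
    cap12 = age_cap_days(birth_date, 12)
    cap3 = age_cap_days(birth_date, 3)
    incident, dx_ages, rx_ages = _asthma_incident(dx, rx, birth_date, codes, cap12)
    post36 = bool((dx_ages >= cap3).any() or (rx_ages >= cap3).any())
    is_case = incident is not None and post36
    return OutcomeAscertainment("asthma_3plus", is_case, incident if is_case else None)


def ascertain_wheeze(dx, rx, birth_date, codes: CodeSetConfig = CodeSetConfig()) -> OutcomeAscertainment:
    """Early-life wheeze 0-36 months: a single qualifying event suffices."""
    cap3 = age_cap_days(birth_date, 3)
    dx_ages = _event_ages(dx, "event_date", "icd10_code", birth_date, codes.wheeze_icd)
    rx_ages = _event_ages(rx, "dispense_date", "atc_code", birth_date, codes.wheeze_atc)
    ages = np.concatenate([dx_ages[dx_ages < cap3], rx_ages[rx_ages < cap3]])
    is_case = ages.size > 0
    return OutcomeAscertainment("wheeze", is_case, int(ages.min()) if is_case else None)


def ascertain_parental_asthma(
    dx,
    rx,
    codes: CodeSetConfig = CodeSetConfig(),
    study_window: tuple = ("2006-01-01", "2022-12-31"),
) -> bool:
    """Asthma rule with no age cap over a parent's events in the study window."""
    start, end = (pd.Timestamp(study_window[0]), pd.Timestamp(study_window[1]))

    def _restrict(events, date_col):
        if events is None or len(events) == 0:
            return events
        if not isinstance(events, pd.DataFrame):
            events = pd.DataFrame(
                [e if isinstance(e, dict) else vars(e) for e in events]
            )
        dates = pd.to_datetime(events[date_col])
        return events[(dates >= start) & (dates <= end)]

    dx = _restrict(dx, "event_date")
    rx = _restrict(rx, "dispense_date")
    # ages measured from the window start; no cap, so the origin is arbitrary
    incident, _, _ = _asthma_incident(dx, rx, start, codes, None)
    return incident is not None


# ---------------------------------------------------------------------------
# vectorised cohort-level engine
# ---------------------------------------------------------------------------

def _tag_events(events: pd.DataFrame, date_col: str, code_col: str,
                persons: pd.DataFrame, prefixes: Sequence[str],
                check_birth: bool = True) -> pd.DataFrame:
    """Join events to births, compute ages, filter to matching code prefixes."""
    if events is None or events.empty:
        return pd.DataFrame(columns=["person_id", "age_days"])
    ev = events.merge(
        persons[["person_id", "birth_date"]], on="person_id", how="inner"
    )
    ages = (pd.to_datetime(ev[date_col]) - pd.to_datetime(ev["birth_date"])).dt.days
    if check_birth and len(ages) and ages.min() < 0:
        bad = ev.loc[ages < 0, "person_id"].unique()[:5]
        raise EventBeforeBirthError(f"events before birth for {list(bad)}")
    keep = ev[code_col].astype(str).str.startswith(tuple(prefixes)).to_numpy()
    return pd.DataFrame({"person_id": ev["person_id"].to_numpy()[keep],
                         "age_days": ages.to_numpy()[keep]})


def _caps_frame(persons: pd.DataFrame) -> pd.DataFrame:
    birth = pd.to_datetime(persons["birth_date"])
    return pd.DataFrame({
        "person_id": persons["person_id"].to_numpy(),
        "cap3": ((birth + pd.DateOffset(years=3)) - birth).dt.days.to_numpy(),
        "cap12": ((birth + pd.DateOffset(years=12)) - birth).dt.days.to_numpy(),
    })


def _asthma_rx_first(rx_tagged: pd.DataFrame, caps: pd.DataFrame,
                     window: Optional[int]) -> pd.Series:
    """Per person, earliest capped dispensation with a later repeat (vectorised
    for the unlimited-window default; per-group scan otherwise)."""
    rx = rx_tagged.merge(caps, on="person_id")
    rx = rx[rx["age_days"] < rx["cap12"]]
    if rx.empty:
        return pd.Series(dtype=float)
    if window is None:
        g = rx.groupby("person_id")["age_days"]
        first, last = g.min(), g.max()
        qualified = first[last > first]  # >=2 dispensations on distinct days
        return qualified.astype(float)
    out = {}
    for pid, grp in rx.groupby("person_id"):
        f = _first_repeat_qualified(np.sort(grp["age_days"].to_numpy()), window)
        if f is not None:
            out[pid] = float(f)
    return pd.Series(out, dtype=float)


def ascertain_cohort(
    diagnoses: pd.DataFrame,
    dispensations: pd.DataFrame,
    persons: pd.DataFrame,
    codes: CodeSetConfig = CodeSetConfig(),
) -> pd.DataFrame:
    """Apply all three outcome algorithms to every child.

    Returns a long DataFrame: ``person_id``, ``outcome``, ``is_case``,
    ``incident_age_days`` (NaN for non-cases).  Equivalent to the per-child
    functions applied row by row (property-tested), but vectorised.
    """
    caps = _caps_frame(persons)
    pid = caps["person_id"]

    child_ids = set(persons["person_id"])
    dx = diagnoses[diagnoses["person_id"].isin(child_ids)] if diagnoses is not None and not diagnoses.empty else diagnoses
    rx = dispensations[dispensations["person_id"].isin(child_ids)] if dispensations is not None and not dispensations.empty else dispensations

    dx_asthma = _tag_events(dx, "event_date", "icd10_code", persons, codes.asthma_icd)
    rx_asthma = _tag_events(rx, "dispense_date", "atc_code", persons, codes.asthma_atc)
    dx_wheeze = _tag_events(dx, "event_date", "icd10_code", persons, codes.wheeze_icd)
    rx_wheeze = _tag_events(rx, "dispense_date", "atc_code", persons, codes.wheeze_atc)

    # --- asthma ---
    dxa = dx_asthma.merge(caps, on="person_id")
    dxa = dxa[dxa["age_days"] < dxa["cap12"]]
    dx_first = dxa.groupby("person_id")["age_days"].min()
    rx_first = _asthma_rx_first(rx_asthma, caps, codes.repeat_window_days)
    asthma_incident = pd.concat([dx_first.astype(float), rx_first], axis=1).min(axis=1)
    asthma_incident = asthma_incident.reindex(pid).to_numpy()

    # --- post-36-month qualifying event (for asthma 3+) ---
    evs = pd.concat([dx_asthma, rx_asthma], ignore_index=True).merge(caps, on="person_id")
    evs = evs[(evs["age_days"] >= evs["cap3"]) & (evs["age_days"] < evs["cap12"])]
    post36 = pd.Series(True, index=evs["person_id"].unique()).reindex(pid, fill_value=False).to_numpy(dtype=bool)

    # --- wheeze ---
    wh = pd.concat([dx_wheeze, rx_wheeze], ignore_index=True).merge(caps, on="person_id")
    wh = wh[wh["age_days"] < wh["cap3"]]
    wheeze_incident = wh.groupby("person_id")["age_days"].min().reindex(pid).to_numpy()

    frames = []
    for outcome, incident, case in (
        ("wheeze", wheeze_incident, ~np.isnan(wheeze_incident)),
        ("asthma", asthma_incident, ~np.isnan(asthma_incident)),
        (
            "asthma_3plus",
            np.where(post36, asthma_incident, np.nan),
            (~np.isnan(asthma_incident)) & post36,
        ),
    ):
        frames.append(pd.DataFrame({
            "person_id": pid,
            "outcome": outcome,
            "is_case": case,
            "incident_age_days": incident,
        }))
    return pd.concat(frames, ignore_index=True)


def parental_asthma_cohort(
    persons: pd.DataFrame,
    diagnoses: pd.DataFrame,
    dispensations: pd.DataFrame,
    codes: CodeSetConfig = CodeSetConfig(),
    study_window: tuple = ("2006-01-01", "2022-12-31"),
) -> pd.Series:
    """Child-level parental-asthma indicator: OR over both parents.

    Parent events are looked up in the same diagnosis/dispensation registers
    by the parent's person id.
    """
    start, end = pd.Timestamp(study_window[0]), pd.Timestamp(study_window[1])
    parent_ids = set(persons["mother_id"]) | set(persons["father_id"])

    def _parent_events(events, date_col):
        if events is None or events.empty:
            return pd.DataFrame(columns=["person_id", date_col]).assign(age_days=[])
        ev = events[events["person_id"].isin(parent_ids)].copy()
        dates = pd.to_datetime(ev[date_col])
        ev = ev[(dates >= start) & (dates <= end)]
        ev["age_days"] = (pd.to_datetime(ev[date_col]) - start).dt.days
        return ev

    dxp = _parent_events(diagnoses, "event_date")
    rxp = _parent_events(dispensations, "dispense_date")

    case_parents: set = set()
    if not dxp.empty:
        keep = dxp["icd10_code"].astype(str).str.startswith(tuple(codes.asthma_icd))
        case_parents |= set(dxp.loc[keep, "person_id"])
    if not rxp.empty:
        keep = rxp["atc_code"].astype(str).str.startswith(tuple(codes.asthma_atc))
        rxa = rxp[keep]
        if codes.repeat_window_days is None:
            g = rxa.groupby("person_id")["age_days"]
            case_parents |= set(g.min()[g.max() > g.min()].index)
        else:
            for pid_, grp in rxa.groupby("person_id"):
                if _first_repeat_qualified(
                    np.sort(grp["age_days"].to_numpy()), codes.repeat_window_days
                ) is not None:
                    case_parents.add(pid_)

    flag = persons["mother_id"].isin(case_parents) | persons["father_id"].isin(case_parents)
    return pd.Series(flag.to_numpy(), index=persons["person_id"].to_numpy(), name="parental_asthma")
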