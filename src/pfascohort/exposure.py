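"""Address-based four-level prenatal PFAS exposure proxy.

A mother's drinking-water PFAS exposure is approximated from her registered
address during the five calendar years preceding the year of delivery (or
serum sampling, for the biomarker validation cohort).  Each address-year
carries two flags: whether the address was in Ronneby at all, and whether it
was supplied by the AFFF-contaminated waterworks.  The proxy is ordinal:

* ``very_high``    -- contaminated water in *all five* window years;
* ``high``         -- contaminated water in at least one, but not all five;
* ``intermediate`` -- lived in Ronneby during the window, never on
  contaminated water;
* ``background``   -- lived in Blekinge but never in Ronneby.

Window years with no address record count as "not in Ronneby"; a window with
no records at all is unclassifiable and raises, so silent data problems do
not masquerade as background exposure.  Duplicate records within a year are
merged by logical OR of both flags.
"""

from __future__ import annotations

import enum
from typing import Iterable

import numpy as np
import pandas as pd

__all__ = [
    "ExposureCategory",
    "UnclassifiableError",
    "classify_prenatal_exposure",
    "classify_at_sampling",
    "classify_cohort",
    "WINDOW_LENGTH_YEARS",
]

WINDOW_LENGTH_YEARS = 5


class UnclassifiableError(ValueError):
    """No address record exists in the five-year window."""


class ExposureCategory(enum.IntEnum):
    """Ordered exposure proxy; comparisons follow the ordering of exposure."""

    BACKGROUND = 0
    INTERMEDIATE = 1
    HIGH = 2
    VERY_HIGH = 3

    @property
    def label(self) -> str:
        return self.name.lower()

    @classmethod
    def from_label(cls, label: str) -> "ExposureCategory":
        return cls[label.upper()]


def _window_flags(history, window_years: range) -> tuple[list[bool], list[bool], int]:
    """Per-year (in_ronneby, contaminated) OR-merged flags over the window.

    Accepts a DataFrame with columns (calendar_year, in_ronneby,
    contaminated_water) or an iterable of objects/mappings with those fields.
    Returns (ronneby flags, contaminated flags, n recorded window years).
    """
    if isinstance(history, pd.DataFrame):
        years = history["calendar_year"].to_numpy()
        ronneby = history["in_ronneby"].to_numpy(dtype=bool)
        contaminated = history["contaminated_water"].to_numpy(dtype=bool)
        records = zip(years, ronneby, contaminated)
    else:
        records = []
        for rec in history:
            if isinstance(rec, dict):
                records.append(
                    (rec["calendar_year"], bool(rec["in_ronneby"]), bool(rec["contaminated_water"]))
                )
            else:
                records.append(
                    (rec.calendar_year, bool(rec.in_ronneby), bool(rec.contaminated_water))
                )

    ron = {y: False for y in window_years}
    con = {y: False for y in window_years}
    seen: set[int] = set()
    for year, in_ron, contam in records:
        year = int(year)
        if year not in ron:
            continue
        seen.add(year)
        # contaminated water implies a Ronneby address
        ron[year] = ron[year] or in_ron or contam
        con[year] = con[year] or contam
    return [ron[y] for y in window_years], [con[y] for y in window_years], len(seen)


def _classify_window(history, window_years: range) -> ExposureCategory:
    ronneby, contaminated, n_recorded = _window_flags(history, window_years)
    if n_recorded == 0:
        raise UnclassifiableError(
            f"no address record in window years {window_years.start}-{window_years.stop - 1}"
        )
    if all(contaminated):
        return ExposureCategory.VERY_HIGH
    if any(contaminated):
        return ExposureCategory.HIGH
    if any(ronneby):
        return ExposureCategory.INTERMEDIATE
    return ExposureCategory.BACKGROUND


def classify_prenatal_exposure(history, delivery_year: int) -> ExposureCategory:
    """Classify a mother-child pair from maternal address history.

    The window is the five calendar years preceding the year of delivery,
    ``[delivery_year - 5, delivery_year - 1]``.
    """
    return _classify_window(history, range(delivery_year - WINDOW_LENGTH_YEARS, delivery_year))


def classify_at_sampling(history, sampling_year: int) -> ExposureCategory:
    """Same rule with the window anchored at the serum sampling year."""
    return _classify_window(history, range(sampling_year - WINDOW_LENGTH_YEARS, sampling_year))


def classify_cohort(
    addresses: pd.DataFrame,
    persons: pd.DataFrame,
    on_unclassifiable: str = "raise",
) -> pd.DataFrame:
    """Vectorised per-child classification for a whole cohort.

    Parameters
    ----------
    addresses
        Mother address-year register: columns ``person_id`` (the mother),
        ``calendar_year``, ``in_ronneby``, ``contaminated_water``.
    persons
        Birth register with ``person_id``, ``mother_id`` and ``birth_date``
        (the delivery year is taken from the birth date).
    on_unclassifiable
        ``"raise"`` (default) or ``"drop"`` children whose mothers have no
        recorded window year.

    Returns
    -------
    DataFrame with ``person_id``, ``exposure`` (category label),
    ``n_window_years_recorded`` and a ``partial_window`` flag marking windows
    with 1-4 recorded years (classified under the "absent year = not in
    Ronneby" rule, surfaced as metadata rather than hidden).
    """
    if on_unclassifiable not in ("raise", "drop"):
        raise ValueError("on_unclassifiable must be 'raise' or 'drop'")

    birth_dates = pd.to_datetime(persons["birth_date"])
    children = pd.DataFrame(
        {
            "person_id": persons["person_id"].to_numpy(),
            "mother_id": persons["mother_id"].to_numpy(),
            "delivery_year": birth_dates.dt.year.to_numpy(),
        }
    )
    # explode each child into its five window years and left-join the register
    offsets = np.arange(-WINDOW_LENGTH_YEARS, 0)
    window = children.loc[children.index.repeat(WINDOW_LENGTH_YEARS)].reset_index(drop=True)
    window["calendar_year"] = window["delivery_year"].to_numpy() + np.tile(
        offsets, len(children)
    )

    addr = (
        addresses.groupby(["person_id", "calendar_year"], as_index=False)
        .agg(in_ronneby=("in_ronneby", "any"), contaminated_water=("contaminated_water", "any"))
        .rename(columns={"person_id": "mother_id"})
    )
    addr["in_ronneby"] = addr["in_ronneby"] | addr["contaminated_water"]
    merged = window.merge(addr, on=["mother_id", "calendar_year"], how="left")
    merged["recorded"] = merged["in_ronneby"].notna()
    merged["in_ronneby"] = merged["in_ronneby"].fillna(False).astype(bool)
    merged["contaminated_water"] = merged["contaminated_water"].fillna(False).astype(bool)

    agg = merged.groupby("person_id", sort=False).agg(
        n_recorded=("recorded", "sum"),
        n_contaminated=("contaminated_water", "sum"),
        n_ronneby=("in_ronneby", "sum"),
    )
    agg = agg.loc[children["person_id"]]

    missing = agg["n_recorded"] == 0
    if missing.any():
        if on_unclassifiable == "raise":
            bad = agg.index[missing].tolist()[:5]
            raise UnclassifiableError(
                f"{int(missing.sum())} children have no recorded window year (e.g. {bad})"
            )
        agg = agg[~missing]

    level = np.select(
        [
            agg["n_contaminated"] == WINDOW_LENGTH_YEARS,
            agg["n_contaminated"] >= 1,
            agg["n_ronneby"] >= 1,
        ],
        [
            ExposureCategory.VERY_HIGH,
            ExposureCategory.HIGH,
            ExposureCategory.INTERMEDIATE,
        ],
        default=ExposureCategory.BACKGROUND,
    )
    return pd.DataFrame(
        {
            "person_id": agg.index.to_numpy(),
            "exposure": [ExposureCategory(lv).label for lv in level],
            "n_window_years_recorded": agg["n_recorded"].to_numpy(dtype=int),
            "partial_window": (agg["n_recorded"] < WINDOW_LENGTH_YEARS).to_numpy(),
        }
    )
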