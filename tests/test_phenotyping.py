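"""Outcome phenotyping rules, boundary conventions, and a brute-force oracle."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from pfascohort import (
    CodeSetConfig,
    ascertain_asthma,
    ascertain_asthma_3plus,
    ascertain_cohort,
    ascertain_parental_asthma,
    ascertain_wheeze,
)
from pfascohort.phenotyping import EventBeforeBirthError, age_cap_days

BIRTH = "2008-01-15"
CODES = CodeSetConfig()


def dx(*day_code):
    return pd.DataFrame({
        "person_id": "x",
        "event_date": [str(pd.Timestamp(BIRTH) + pd.Timedelta(days=d)) for d, _ in day_code],
        "icd10_code": [c for _, c in day_code],
        "source": "outpatient",
    })


def rx(*days):
    return pd.DataFrame({
        "person_id": "x",
        "dispense_date": [str(pd.Timestamp(BIRTH) + pd.Timedelta(days=d)) for d in days],
        "atc_code": "R03A",
    })


@pytest.mark.parametrize(
    "dx_events,rx_days,is_case,incident",
    [
        # one diagnosis is enough; incidence at the diagnosis
        ([(1500, "J45")], [], True, 1500),
        # a single dispensation never qualifies
        ([], [400], False, None),
        # repeat-confirmed dispensations: first dispensation dates the incidence
        ([], [400, 620], True, 400),
        # repeat on the same day does not confirm
        ([], [400, 400], False, None),
        # events after the 12th birthday are outside the algorithm
        ([(4500, "J45")], [], False, None),
        # wheeze-only codes never qualify for asthma
        ([(300, "J21")], [], False, None),
    ],
)
def test_asthma_rule(dx_events, rx_days, is_case, incident):
    res = ascertain_asthma(dx(*dx_events) if dx_events else None, rx(*rx_days) if rx_days else None, BIRTH, CODES)
    assert res.is_case == is_case
    assert res.incident_age_days == incident


@pytest.mark.parametrize(
    "dx_events,rx_days,is_case,incident",
    [
        # confirmed asthma but nothing after 36 months -> not strict asthma
        ([], [400, 620], False, None),
        # a third dispensation past 36 months confirms, incidence unchanged
        ([], [400, 620, 1300], True, 400),
        # one post-36-month diagnosis satisfies both clauses
        ([(2000, "J45")], [], True, 2000),
    ],
)
def test_strict_asthma_rule(dx_events, rx_days, is_case, incident):
    res = ascertain_asthma_3plus(dx(*dx_events) if dx_events else None, rx(*rx_days) if rx_days else None, BIRTH, CODES)
    assert res.is_case == is_case
    assert res.incident_age_days == incident


@pytest.mark.parametrize(
    "dx_events,rx_days,is_case,incident",
    [
        # a lower-respiratory-infection diagnosis in infancy
        ([(300, "J21")], [], True, 300),
        # an asthma diagnosis past the 36-month cap is not wheeze
        ([(1200, "J45")], [], False, None),
        # a single unrepeated dispensation suffices for wheeze
        ([], [100], True, 100),
    ],
)
def test_wheeze_rule(dx_events, rx_days, is_case, incident):
    res = ascertain_wheeze(dx(*dx_events) if dx_events else None, rx(*rx_days) if rx_days else None, BIRTH, CODES)
    assert res.is_case == is_case
    assert res.incident_age_days == incident


def test_birthday_boundary_convention():
    """An event exactly on the 3rd birthday is 'after 36 months'."""
    cap3 = age_cap_days(BIRTH, 3)
    # not wheeze (cap is strict) ...
    assert not ascertain_wheeze(dx((cap3, "J45")), None, BIRTH, CODES).is_case
    # ... but it does confirm strict asthma
    res = ascertain_asthma_3plus(dx((cap3, "J45")), None, BIRTH, CODES)
    assert res.is_case and res.incident_age_days == cap3


def test_event_before_birth_raises():
    bad = pd.DataFrame({
        "person_id": "x", "event_date": ["2007-12-31"], "icd10_code": ["J45"],
        "source": "outpatient",
    })
    with pytest.raises(EventBeforeBirthError):
        ascertain_asthma(bad, None, BIRTH, CODES)


def test_parental_asthma_rule():
    win = ("2006-01-01", "2022-12-31")
    father_dx = pd.DataFrame({
        "person_id": "f", "event_date": ["2014-05-01"], "icd10_code": ["J45"],
        "source": "outpatient",
    })
    assert ascertain_parental_asthma(father_dx, None, CODES, win)
    assert not ascertain_parental_asthma(None, None, CODES, win)
    single_rx = pd.DataFrame({
        "person_id": "m", "dispense_date": ["2014-05-01"], "atc_code": ["R03"],
    })
    assert not ascertain_parental_asthma(None, single_rx, CODES, win)
    # events outside the study window are invisible
    old_dx = father_dx.assign(event_date=["2005-01-01"])
    assert not ascertain_parental_asthma(old_dx, None, CODES, win)


# --- brute-force oracle ------------------------------------------------------

def oracle_asthma(dx_days, rx_days, cap12, window=None):
    """Direct scan over all event pairs/singletons."""
    candidates = [d for d in dx_days if d < cap12]
    firsts = []
    rx_in = sorted(d for d in rx_days if d < cap12)
    for i, a in enumerate(rx_in):
        for b in rx_in[i + 1:]:
            if b > a and (window is None or b - a <= window):
                firsts.append(a)
                break
    allc = candidates + firsts
    return (min(allc) if allc else None)


def oracle_wheeze(dx_days_wheeze, rx_days, cap3):
    evs = [d for d in dx_days_wheeze + rx_days if d < cap3]
    return min(evs) if evs else None


event_days = st.lists(st.integers(0, 5000), max_size=6)


@given(event_days, event_days, st.sampled_from([None, 180, 365]))
@settings(max_examples=250, deadline=None, derandomize=True)
def test_asthma_matches_brute_force_scan(dx_days, rx_days, window):
    codes = CodeSetConfig(repeat_window_days=window)
    cap12 = age_cap_days(BIRTH, 12)
    res = ascertain_asthma(
        dx(*[(d, "J45") for d in dx_days]) if dx_days else None,
        rx(*rx_days) if rx_days else None,
        BIRTH, codes,
    )
    expected = oracle_asthma(dx_days, rx_days, cap12, window)
    assert res.incident_age_days == expected


@given(event_days, event_days)
@settings(max_examples=250, deadline=None, derandomize=True)
def test_monotonicity_and_strict_subset(dx_days, rx_days):
    """Adding events can only create cases or move incidence earlier; strict
    asthma is a subset of asthma with the same incident date."""
    d = dx(*[(v, "J45") for v in dx_days]) if dx_days else None
    r = rx(*rx_days) if rx_days else None
    res = ascertain_asthma(d, r, BIRTH, CODES)
    res3 = ascertain_asthma_3plus(d, r, BIRTH, CODES)
    if res3.is_case:
        assert res.is_case and res3.incident_age_days == res.incident_age_days

    extra_dx = dx(*([(v, "J45") for v in dx_days] + [(900, "J45")]))
    grown = ascertain_asthma(extra_dx, r, BIRTH, CODES)
    assert grown.is_case >= res.is_case
    if res.is_case:
        assert grown.incident_age_days <= res.incident_age_days


def test_vectorised_engine_matches_per_child(noisy_bundle):
    """The cohort engine agrees with the scalar rules child by child."""
    persons = noisy_bundle.persons
    asc = ascertain_cohort(noisy_bundle.diagnoses, noisy_bundle.dispensations, persons)
    sample = persons.sample(40, random_state=1)
    fns = {"wheeze": ascertain_wheeze, "asthma": ascertain_asthma,
           "asthma_3plus": ascertain_asthma_3plus}
    asc_idx = asc.set_index(["person_id", "outcome"])
    for _, child in sample.iterrows():
        cdx = noisy_bundle.diagnoses[noisy_bundle.diagnoses["person_id"] == child["person_id"]]
        crx = noisy_bundle.dispensations[noisy_bundle.dispensations["person_id"] == child["person_id"]]
        for outcome, fn in fns.items():
            scalar = fn(cdx, crx, child["birth_date"])
            row = asc_idx.loc[(child["person_id"], outcome)]
            assert bool(row["is_case"]) == scalar.is_case
            if scalar.is_case:
                assert int(row["incident_age_days"]) == scalar.incident_age_days
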