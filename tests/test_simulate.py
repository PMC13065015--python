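"""Synthetic register generator: determinism, design margins, calibration."""

import numpy as np
import pandas as pd
import pytest

from pfascohort import (
    InvalidConfigError,
    SimConfig,
    classify_cohort,
    generate_biomarker_cohort,
    generate_bundle,
    generate_population,
)


def test_empty_cohort_has_correct_schemas():
    bundle = generate_bundle(SimConfig(n_children=0, seed=1))
    assert len(bundle.persons) == 0
    assert list(bundle.persons.columns)[:4] == ["person_id", "mother_id", "father_id", "birth_date"]
    assert {"person_id", "calendar_year", "in_ronneby", "contaminated_water"} <= set(
        bundle.addresses.columns
    )
    assert len(bundle.diagnoses) == 0 and len(bundle.dispensations) == 0


@pytest.mark.parametrize(
    "bad",
    [
        {"n_children": -5},
        {"group_proportions": {"background": 0.5, "intermediate": 0.2, "high": 0.2, "very_high": 0.2}},
        {"sibling_rate": 1.4},
        {"true_hr": {"asthma": {"very_high": -2.0}, "wheeze": {}}},
    ],
)
def test_invalid_configs_raise(bad):
    with pytest.raises(InvalidConfigError):
        generate_bundle(SimConfig(**bad))


def test_same_seed_is_byte_identical(tmp_path):
    cfg = SimConfig(n_children=400, seed=9)
    a, b = generate_bundle(cfg), generate_bundle(cfg)
    for name in ("persons", "addresses", "diagnoses", "dispensations", "vitals", "latent"):
        pd.testing.assert_frame_equal(getattr(a, name), getattr(b, name))
    a.write_csv(tmp_path / "a")
    b.write_csv(tmp_path / "b")
    for f in (tmp_path / "a").iterdir():
        assert f.read_bytes() == (tmp_path / "b" / f.name).read_bytes()


def test_csv_round_trip(tmp_path):
    cfg = SimConfig(n_children=200, seed=2)
    bundle = generate_bundle(cfg)
    bundle.write_csv(tmp_path)
    from pfascohort import RegisterBundle

    back = RegisterBundle.read_csv(tmp_path)
    assert len(back.persons) == 200
    assert back.config.n_children == 200


def test_group_counts_within_binomial_bounds():
    """Group sizes at the design cohort size stay inside 99% binomial bands
    around the target 194/479/1,591/9,224 out of 11,488."""
    cfg = SimConfig(n_children=11488, seed=42)
    bundle = generate_population(cfg)
    counts = bundle.latent["exposure_group"].value_counts()
    targets = {"very_high": 194, "high": 479, "intermediate": 1591, "background": 9224}
    for group, k in targets.items():
        p = k / 11488
        sd = np.sqrt(11488 * p * (1 - p))
        assert abs(counts[group] - k) < 2.576 * sd + 25  # clustering slack: mother-level draws


def test_sibling_rate_and_cluster_structure(small_bundle):
    persons = small_bundle.persons
    fam = persons.groupby("mother_id").size()
    share = (fam[fam >= 2].sum()) / len(persons)
    assert abs(share - 0.24) < 0.03
    # siblings share the exposure category (mother-level assignment)
    lat = small_bundle.latent.set_index("person_id")
    merged = persons.set_index("person_id").join(lat["exposure_group"])
    assert (merged.groupby("mother_id")["exposure_group"].nunique() == 1).all()


def test_address_round_trip_property(noisy_bundle):
    result = classify_cohort(noisy_bundle.addresses, noisy_bundle.persons)
    truth = noisy_bundle.latent.set_index("person_id")["exposure_group"]
    assert (result.set_index("person_id")["exposure"].reindex(truth.index) == truth).all()


def test_background_incidence_hits_calibration_target():
    cfg = SimConfig(n_children=20000, seed=11, noise_rate=0.0)
    lat = generate_bundle(cfg).latent
    bg = lat["exposure_group"] == "background"
    for outcome, target in (("asthma", 0.17), ("wheeze", 0.18)):
        p = lat.loc[bg, f"{outcome}_case"].mean()
        mc = 3 * np.sqrt(target * (1 - target) / bg.sum())
        assert abs(p - target) < mc


def test_null_hazard_gives_symmetric_groups():
    """With all group HRs at 1, group incidences fluctuate around a common value."""
    diffs = []
    props = {g: 0.25 for g in ("background", "intermediate", "high", "very_high")}
    for seed in range(20):
        cfg = SimConfig(
            n_children=500, seed=seed, noise_rate=0.0, missing_rate={},
            group_proportions=props,
            true_hr={"wheeze": {}, "asthma": {}},  # empty = all 1.0
        )
        lat = generate_bundle(cfg).latent
        inc = lat.groupby("exposure_group")["asthma_case"].mean()
        diffs.append(inc["very_high"] - inc["background"])
    assert abs(np.mean(diffs)) < 3 * np.std(diffs) / np.sqrt(len(diffs)) + 0.01


def test_extreme_hazard_dominates():
    cfg = SimConfig(
        n_children=4000, seed=8, noise_rate=0.0,
        true_hr={"wheeze": {}, "asthma": {"very_high": 10.0}},
    )
    lat = generate_bundle(cfg).latent
    inc = lat.groupby("exposure_group")["asthma_case"].mean()
    assert inc["very_high"] > inc["background"]


def test_vitals_and_event_stream_invariants(noisy_bundle):
    vit = noisy_bundle.vitals
    assert (vit.groupby("person_id")["kind"].apply(lambda k: (k == "death").sum()) <= 1).all()
    # no child event predates birth or postdates the administrative end
    persons = noisy_bundle.persons.set_index("person_id")
    child_dx = noisy_bundle.diagnoses[
        noisy_bundle.diagnoses["person_id"].isin(persons.index)
    ]
    merged = child_dx.merge(
        persons["birth_date"], left_on="person_id", right_index=True
    )
    ages = (pd.to_datetime(merged["event_date"]) - pd.to_datetime(merged["birth_date"])).dt.days
    assert (ages >= 0).all()
    assert (pd.to_datetime(child_dx["event_date"]) <= pd.Timestamp("2022-12-31")).all()


def test_biomarker_medians_calibrated():
    cfg = SimConfig(seed=13)
    n = {g: 10000 for g in ("background", "intermediate", "high", "very_high")}
    bio = generate_biomarker_cohort(cfg, n_per_group=n)
    med_vh = bio.loc[bio["exposure_group"] == "very_high", "pfhxs_ngml"].median()
    med_bg = bio.loc[bio["exposure_group"] == "background", "pfhxs_ngml"].median()
    assert abs(med_vh - 164.8) / 164.8 < 0.05
    assert abs(med_bg - 0.8) / 0.8 < 0.05


def test_biomarker_zero_variance_collapses_to_median():
    bio = generate_biomarker_cohort(SimConfig(seed=1), sigma_scale=0.0)
    vh = bio[bio["exposure_group"] == "very_high"]
    assert (vh["pfhxs_ngml"] == 164.8).all()


def test_biomarker_concentrations_positive_and_ordered(small_bundle):
    bio = generate_biomarker_cohort(SimConfig(seed=5))
    assert (bio[["pfos_ngml", "pfhxs_ngml", "pfoa_ngml"]] > 0).all().all()
    med = bio.groupby("exposure_group")["pfos_ngml"].median()
    assert (
        med["background"] < med["intermediate"] < med["high"] < med["very_high"]
    )


def test_missingness_mar_targets_low_income():
    cfg = SimConfig(n_children=8000, seed=21, mar_income_strength=1.0,
                    missing_rate={"smoking": 0.2})
    persons = generate_population(cfg).persons
    miss = persons["maternal_smoking"].isna()
    assert persons.loc[miss, "family_income"].mean() < persons.loc[~miss, "family_income"].mean()
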