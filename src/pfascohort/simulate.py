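"""Synthetic linked-register generator.

Emulates the statistical structure of an 8-year Swedish county birth cohort
(~11,500-12,600 children, birth years 2006-2013) in which a subset of mothers
drew drinking water from an AFFF-contaminated waterworks:

* four ordered prenatal exposure groups in proportions
  194 / 479 / 1,591 / 9,224 of 11,488 (very high / high / intermediate /
  background), assigned at the mother level;
* maternal address-year histories constructed so the address-window
  classifier recovers the assigned group exactly (round-trip property);
* sibling clustering: by default 24% of children share a mother with another
  cohort child;
* covariate distributions shifted by exposure group (smoking, parity, sex,
  education, maternal age, foreign-born parent, family income, parental
  asthma), with configurable MCAR/MAR missingness;
* latent outcome onsets from a piecewise-constant hazard on age (knots at 36
  months and 6 years) multiplied by group hazard ratios and covariate
  effects, calibrated so the background group hits a target cumulative
  incidence per outcome;
* diagnosis (ICD-10) and dispensation (ATC) event streams that satisfy the
  phenotyping algorithms exactly for latent cases, plus optional noise events
  (isolated dispensations, infant respiratory infections) for non-cases;
* deaths and emigrations at configurable rates; parent event streams driving
  the parental-asthma indicator;
* a serum PFAS biomarker cohort with per-group lognormal concentrations
  calibrated to observed medians/IQRs.

Everything is reproducible bit-for-bit from (config, seed).
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .exposure import ExposureCategory

__all__ = [
    "SimConfig",
    "RegisterBundle",
    "InvalidConfigError",
    "GROUP_LABELS",
    "generate_population",
    "generate_health_events",
    "generate_biomarker_cohort",
    "generate_bundle",
    "latent_followups",
]

GROUP_LABELS = ("background", "intermediate", "high", "very_high")

# latent-hazard shape: piecewise-constant on age with knots at 36 months and
# 6 years; relative levels chosen to give an early-childhood-weighted onset
# distribution for asthma and a flat infant hazard for wheeze
HAZARD_KNOTS_DAYS = (1096.0, 2192.0)
ASTHMA_HAZARD_LEVELS = (1.3, 1.0, 0.8)

# per-group covariate margins (background, intermediate, high, very_high):
# observed baseline characteristics of the cohort the generator emulates
_MARGINS = {
    "smoking": (0.072, 0.083, 0.171, 0.098),
    "multiparous": (0.581, 0.571, 0.541, 0.753),
    "female": (0.479, 0.502, 0.497, 0.448),
    # education P(primary, upper secondary, post secondary)
    "education": (
        (0.194, 0.311, 0.495),
        (0.193, 0.319, 0.488),
        (0.282, 0.365, 0.353),
        (0.320, 0.407, 0.273),
    ),
    "maternal_age": ((30.1, 5.3), (30.1, 5.2), (27.7, 5.6), (30.9, 6.0)),  # mean, sd
    "foreign_born": (0.201, 0.172, 0.157, 0.093),
    "income": ((3.8, 1.19), (3.8, 1.19), (3.5, 1.04), (3.7, 1.04)),  # 1e5 SEK
    "parental_asthma": (0.170, 0.157, 0.221, 0.191),
}

# serum PFAS (ng/mL) median and [q1, q3] per group, per analyte, from the
# biomarker validation cohort the generator emulates
BIOMARKER_CALIBRATION = {
    "pfos_ngml": {
        "background": (3.6, 2.6, 4.8),
        "intermediate": (47.7, 30.8, 121.1),
        "high": (137.4, 80.7, 194.8),
        "very_high": (218.7, 140.4, 344.1),
    },
    "pfhxs_ngml": {
        "background": (0.8, 0.7, 1.1),
        "intermediate": (30.5, 21.3, 102.4),
        "high": (100.0, 64.8, 180.3),
        "very_high": (164.8, 106.1, 283.0),
    },
    "pfoa_ngml": {
        "background": (1.6, 0.8, 1.9),
        "intermediate": (3.8, 2.0, 5.6),
        "high": (7.3, 3.7, 14.2),
        "very_high": (11.8, 7.2, 18.9),
    },
}
BIOMARKER_GROUP_N = {"background": 36, "intermediate": 39, "high": 54, "very_high": 80}


class InvalidConfigError(ValueError):
    """Simulation configuration violates an invariant."""


def _default_group_proportions() -> dict:
    n = 11488
    return {
        "background": 9224 / n,
        "intermediate": 1591 / n,
        "high": 479 / n,
        "very_high": 194 / n,
    }


def _default_true_hr() -> dict:
    # latent group hazard ratios vs background; defaults are the adjusted
    # effect sizes the cohort design targets
    return {
        "wheeze": {"background": 1.0, "intermediate": 0.99, "high": 1.08, "very_high": 0.97},
        "asthma": {"background": 1.0, "intermediate": 0.95, "high": 0.96, "very_high": 1.44},
    }


def _default_covariate_effects() -> dict:
    # log-hazard shifts applied to both outcomes' latent onsets
    return {
        "smoking": np.log(1.4),
        "parental_asthma": np.log(2.0),
        "foreign_born": np.log(0.9),
        "education_per_level": np.log(0.9),
        "sex_male": np.log(1.5),
    }


def _default_missing_rate() -> dict:
    # calibrated so ~91% of children have complete covariates
    return {"smoking": 0.06, "education": 0.02, "income": 0.015}


@dataclasses.dataclass
class SimConfig:
    """Study-design parameters of the synthetic cohort."""

    n_children: int = 12585
    birth_year_range: tuple = (2006, 2013)
    group_proportions: dict = dataclasses.field(default_factory=_default_group_proportions)
    true_hr: dict = dataclasses.field(default_factory=_default_true_hr)
    baseline_cuminc: dict = dataclasses.field(
        default_factory=lambda: {"wheeze": 0.18, "asthma": 0.17}
    )
    # probability that an early-onset (<36 m) asthma case remains active after
    # 36 months; calibrated to the 17% asthma vs 13% strict-asthma mix
    persistence_prob: float = 0.30
    covariate_effects: dict = dataclasses.field(default_factory=_default_covariate_effects)
    sibling_rate: float = 0.24
    missing_rate: dict = dataclasses.field(default_factory=_default_missing_rate)
    mar_income_strength: float = 0.0  # 0 = MCAR; >0 ties missingness to low income
    death_rate: float = 0.002
    emigration_rate: float = 0.03
    noise_rate: float = 0.08
    dx_route_prob: float = 0.3  # P(case ascertained via diagnosis rather than rx)
    shared_frailty_sd: float = 0.0  # optional mother-level log-normal frailty (off)
    admin_end: str = "2022-12-31"
    exact_group_counts: bool = False
    seed: int = 0

    def validate(self) -> None:
        if self.n_children < 0:
            raise InvalidConfigError("n_children must be >= 0")
        props = np.array([self.group_proportions[g] for g in GROUP_LABELS], dtype=float)
        if (props < 0).any() or not np.isclose(props.sum(), 1.0):
            raise InvalidConfigError("group_proportions must be nonnegative and sum to 1")
        for rates in (
            [self.sibling_rate, self.death_rate, self.emigration_rate, self.noise_rate,
             self.persistence_prob, self.dx_route_prob],
            list(self.missing_rate.values()),
            list(self.baseline_cuminc.values()),
        ):
            if any(not (0.0 <= r <= 1.0) for r in rates):
                raise InvalidConfigError("all rates must lie in [0, 1]")
        for outcome, hrs in self.true_hr.items():
            if any(h <= 0 for h in hrs.values()):
                raise InvalidConfigError(f"true_hr[{outcome}] must be > 0")
        y0, y1 = self.birth_year_range
        if y1 < y0:
            raise InvalidConfigError("birth_year_range must be increasing")

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        d["birth_year_range"] = list(d["birth_year_range"])
        return json.dumps(d, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "SimConfig":
        d = json.loads(text)
        if "birth_year_range" in d:
            d["birth_year_range"] = tuple(d["birth_year_range"])
        return cls(**d)


_PERSON_COLS = [
    "person_id", "mother_id", "father_id", "birth_date", "sex", "parity",
    "maternal_smoking", "maternal_education", "maternal_age_at_delivery",
    "foreign_born_parent", "family_income",
]
_ADDRESS_COLS = ["person_id", "calendar_year", "in_ronneby", "contaminated_water"]
_DX_COLS = ["person_id", "event_date", "icd10_code", "source"]
_RX_COLS = ["person_id", "dispense_date", "atc_code"]
_VITAL_COLS = ["person_id", "event_date", "kind"]


@dataclasses.dataclass
class RegisterBundle:
    """The linked synthetic registers plus the latent ground truth."""

    persons: pd.DataFrame
    addresses: pd.DataFrame
    diagnoses: pd.DataFrame
    dispensations: pd.DataFrame
    vitals: pd.DataFrame
    latent: pd.DataFrame
    parents: pd.DataFrame
    config: Optional[SimConfig] = None

    _TABLES = ("persons", "addresses", "diagnoses", "dispensations", "vitals",
               "latent", "parents")

    def write_csv(self, directory) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        for name in self._TABLES:
            getattr(self, name).to_csv(directory / f"{name}.csv", index=False)
        if self.config is not None:
            (directory / "config.json").write_text(self.config.to_json())

    @classmethod
    def read_csv(cls, directory) -> "RegisterBundle":
        directory = Path(directory)
        tables = {name: pd.read_csv(directory / f"{name}.csv") for name in cls._TABLES}
        cfg_path = directory / "config.json"
        config = SimConfig.from_json(cfg_path.read_text()) if cfg_path.exists() else None
        return cls(**tables, config=config)

    def write_parquet(self, directory) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        for name in self._TABLES:
            getattr(self, name).to_parquet(directory / f"{name}.parquet", index=False)
        if self.config is not None:
            (directory / "config.json").write_text(self.config.to_json())


def _rng(config: SimConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence((int(config.seed), stream)))


def _assign_counts(n: int, props: np.ndarray) -> np.ndarray:
    """Largest-remainder deterministic rounding of n*props."""
    raw = n * props
    counts = np.floor(raw).astype(int)
    rem = raw - counts
    for i in np.argsort(-rem)[: n - counts.sum()]:
        counts[i] += 1
    return counts


def generate_population(config: SimConfig) -> RegisterBundle:
    """Generate the birth register, address histories and covariates.

    Group assignment and address history are at the mother level, so siblings
    share an exposure category and the classifier round-trips exactly.
    """
    config.validate()
    rng = _rng(config, 0)
    n = config.n_children
    y0, y1 = config.birth_year_range

    empty = RegisterBundle(
        persons=pd.DataFrame(columns=_PERSON_COLS),
        addresses=pd.DataFrame(columns=_ADDRESS_COLS),
        diagnoses=pd.DataFrame(columns=_DX_COLS),
        dispensations=pd.DataFrame(columns=_RX_COLS),
        vitals=pd.DataFrame(columns=_VITAL_COLS),
        latent=pd.DataFrame(columns=["person_id", "exposure_group"]),
        parents=pd.DataFrame(columns=["parent_id", "role", "asthma_case"]),
        config=config,
    )
    if n == 0:
        return empty

    # --- family structure ---------------------------------------------------
    n_pairs = int(round(config.sibling_rate * n / 2.0))
    n_mothers = n - n_pairs
    mother_idx_of_child = np.concatenate(
        [np.repeat(np.arange(n_pairs), 2), np.arange(n_pairs, n_mothers)]
    )
    birth_order = np.concatenate(
        [np.tile([0, 1], n_pairs), np.zeros(n_mothers - n_pairs, dtype=int)]
    )
    n = len(mother_idx_of_child)  # == config.n_children

    # --- exposure groups at the mother level ---------------------------------
    props = np.array([config.group_proportions[g] for g in GROUP_LABELS])
    if config.exact_group_counts:
        counts = _assign_counts(n_mothers, props)
        mother_group = np.repeat(np.arange(4), counts)
        rng.shuffle(mother_group)
    else:
        mother_group = rng.choice(4, size=n_mothers, p=props)
    group = mother_group[mother_idx_of_child]

    # --- birth dates ----------------------------------------------------------
    birth_year = np.empty(n, dtype=int)
    singles = birth_order == 0
    birth_year[singles] = rng.integers(y0, y1 + 1, size=singles.sum())
    firsts = np.flatnonzero((birth_order == 0) & (mother_idx_of_child < n_pairs))
    seconds = np.flatnonzero(birth_order == 1)
    if len(seconds):
        birth_year[firsts] = rng.integers(y0, max(y0 + 1, y1), size=len(firsts))
        gaps = rng.integers(1, 4, size=len(seconds))
        birth_year[seconds] = np.minimum(birth_year[firsts] + gaps, y1)
    day_of_year = rng.integers(0, 365, size=n)
    birth_date = pd.to_datetime(birth_year.astype(str) + "-01-01") + pd.to_timedelta(
        day_of_year, unit="D"
    )

    # --- covariates ------------------------------------------------------------
    def _per_group_bernoulli(key):
        p = np.array(_MARGINS[key])[group]
        return (rng.random(n) < p).astype(float)

    smoking = _per_group_bernoulli("smoking")
    female = _per_group_bernoulli("female")
    multiparous = _per_group_bernoulli("multiparous")
    multiparous[seconds] = 1.0  # a second cohort child is never firstborn
    foreign = np.empty(n)
    education = np.empty(n)
    income = np.empty(n)
    mat_age = np.empty(n)
    # education / income / foreign-born are traits of the family: shared by
    # siblings (drawn once per mother, indexed through the child mapping)
    m_group = mother_group
    m_foreign = (rng.random(n_mothers) < np.array(_MARGINS["foreign_born"])[m_group]).astype(float)
    edu_probs = np.array([_MARGINS["education"][g] for g in m_group])
    u = rng.random(n_mothers)
    m_education = (u > edu_probs[:, 0]).astype(float) + (
        u > edu_probs[:, :2].sum(axis=1)
    ).astype(float)
    inc_mean = np.array([_MARGINS["income"][g][0] for g in m_group])
    inc_sd = np.array([_MARGINS["income"][g][1] for g in m_group])
    m_income = np.clip(rng.normal(inc_mean, inc_sd), 0.2, None)
    foreign = m_foreign[mother_idx_of_child]
    education = m_education[mother_idx_of_child]
    income = m_income[mother_idx_of_child]
    age_mean = np.array([_MARGINS["maternal_age"][g][0] for g in group])
    age_sd = np.array([_MARGINS["maternal_age"][g][1] for g in group])
    mat_age = np.clip(rng.normal(age_mean, age_sd), 16.0, 55.0)

    # parental asthma: independent parents, each with rate 1 - sqrt(1 - p_child)
    p_child = np.array(_MARGINS["parental_asthma"])[m_group]
    p_parent = 1.0 - np.sqrt(1.0 - p_child)
    mother_case = rng.random(n_mothers) < p_parent
    father_case = rng.random(n_mothers) < p_parent

    # --- identifiers ------------------------------------------------------------
    person_id = np.array([f"C{i:06d}" for i in range(n)])
    mother_id = np.array([f"M{i:06d}" for i in range(n_mothers)])[mother_idx_of_child]
    father_id = np.array([f"F{i:06d}" for i in range(n_mothers)])[mother_idx_of_child]

    persons = pd.DataFrame({
        "person_id": person_id,
        "mother_id": mother_id,
        "father_id": father_id,
        "birth_date": birth_date.strftime("%Y-%m-%d"),
        "sex": np.where(female == 1.0, "F", "M"),
        "parity": np.where(multiparous == 1.0, "multiparous", "primiparous"),
        "maternal_smoking": smoking,
        "maternal_education": education,
        "maternal_age_at_delivery": np.round(mat_age, 1),
        "foreign_born_parent": foreign,
        "family_income": np.round(income, 3),
    })

    # --- covariate missingness ---------------------------------------------------
    col_of = {"smoking": "maternal_smoking", "education": "maternal_education",
              "income": "family_income"}
    if config.mar_income_strength > 0:
        inc_z = (income - income.mean()) / max(income.std(), 1e-9)
        weight = np.exp(-config.mar_income_strength * inc_z)
        weight /= weight.mean()
    else:
        weight = np.ones(n)
    for key, rate in config.missing_rate.items():
        if rate <= 0 or key not in col_of:
            continue
        miss = rng.random(n) < np.clip(rate * weight, 0.0, 1.0)
        persons.loc[miss, col_of[key]] = np.nan

    # --- address histories (classifier round-trips by construction) ---------------
    first = pd.Series(birth_year).groupby(mother_idx_of_child).min().to_numpy()
    last = pd.Series(birth_year).groupby(mother_idx_of_child).max().to_numpy()
    m_first_year, m_last_year = first - 5, last - 1
    addr_rows = {"person_id": [], "calendar_year": [], "in_ronneby": [], "contaminated_water": []}
    unique_mid = np.array([f"M{i:06d}" for i in range(n_mothers)])
    contaminated_years = [set() for _ in range(n_mothers)]
    for child in range(n):
        mi = mother_idx_of_child[child]
        if GROUP_LABELS[group[child]] == "high":
            contaminated_years[mi].add(int(birth_year[child]) - 1)
    for mi in range(n_mothers):
        glabel = GROUP_LABELS[m_group[mi]]
        years = np.arange(m_first_year[mi], m_last_year[mi] + 1)
        in_ron = glabel != "background"
        for yy in years:
            if glabel == "very_high":
                contam = True
            elif glabel == "high":
                contam = int(yy) in contaminated_years[mi]
            else:
                contam = False
            addr_rows["person_id"].append(unique_mid[mi])
            addr_rows["calendar_year"].append(int(yy))
            addr_rows["in_ronneby"].append(in_ron)
            addr_rows["contaminated_water"].append(contam)
    addresses = pd.DataFrame(addr_rows)

    latent = pd.DataFrame({
        "person_id": person_id,
        "exposure_group": np.array(GROUP_LABELS)[group],
        "true_smoking": smoking,
        "true_education": education,
        "true_income": np.round(income, 3),
        "sex_male": (female == 0.0).astype(int),
        "parental_asthma": (mother_case | father_case)[mother_idx_of_child].astype(int),
        "foreign_born": foreign.astype(int),
    })

    parents = pd.DataFrame({
        "parent_id": np.concatenate([
            np.array([f"M{i:06d}" for i in range(n_mothers)]),
            np.array([f"F{i:06d}" for i in range(n_mothers)]),
        ]),
        "role": ["mother"] * n_mothers + ["father"] * n_mothers,
        "asthma_case": np.concatenate([mother_case, father_case]).astype(int),
    })

    return RegisterBundle(
        persons=persons,
        addresses=addresses,
        diagnoses=pd.DataFrame(columns=_DX_COLS),
        dispensations=pd.DataFrame(columns=_RX_COLS),
        vitals=pd.DataFrame(columns=_VITAL_COLS),
        latent=latent,
        parents=parents,
        config=config,
    )


# ---------------------------------------------------------------------------
# latent hazard machinery
# ---------------------------------------------------------------------------

def _cumhaz_shape(t: np.ndarray, levels=ASTHMA_HAZARD_LEVELS) -> np.ndarray:
    """Unit-scale cumulative hazard of the piecewise-constant shape."""
    k1, k2 = HAZARD_KNOTS_DAYS
    r1, r2, r3 = levels
    t = np.asarray(t, dtype=float)
    return (
        r1 * np.minimum(t, k1)
        + r2 * np.clip(t - k1, 0.0, k2 - k1)
        + r3 * np.clip(t - k2, 0.0, None)
    )


def _cumhaz_shape_inv(v: np.ndarray, levels=ASTHMA_HAZARD_LEVELS) -> np.ndarray:
    k1, k2 = HAZARD_KNOTS_DAYS
    r1, r2, r3 = levels
    v = np.asarray(v, dtype=float)
    v1 = r1 * k1
    v2 = v1 + r2 * (k2 - k1)
    return np.select(
        [v <= v1, v <= v2],
        [v / r1, k1 + (v - v1) / r2],
        default=k2 + (v - v2) / r3,
    )


def _solve_scale(target: float, mult: np.ndarray, shape_at_h: np.ndarray,
                 offset: np.ndarray | float = 0.0) -> float:
    """Solve for c:  mean(1 - exp(-(c * mult * shape_at_h + offset))) = target."""

    def f(c):
        return float(np.mean(1.0 - np.exp(-(c * mult * shape_at_h + offset)))) - target

    if f(0.0) >= 0.0:
        warnings.warn("baseline incidence target already exceeded at zero hazard scale")
        return 1e-12
    hi = 1e-9
    while f(hi) < 0.0 and hi < 1e3:
        hi *= 10.0
    return brentq(f, 0.0, hi, xtol=1e-14)


def _covariate_multiplier(latent: pd.DataFrame, effects: dict) -> np.ndarray:
    lp = (
        effects.get("smoking", 0.0) * latent["true_smoking"].to_numpy()
        + effects.get("parental_asthma", 0.0) * latent["parental_asthma"].to_numpy()
        + effects.get("foreign_born", 0.0) * latent["foreign_born"].to_numpy()
        + effects.get("education_per_level", 0.0) * latent["true_education"].to_numpy()
        + effects.get("sex_male", 0.0) * latent["sex_male"].to_numpy()
    )
    return np.exp(lp)


def generate_health_events(
    bundle: RegisterBundle, config: SimConfig, emit_events: bool = True
) -> RegisterBundle:
    """Draw latent onsets, deaths/emigrations, and emit event streams.

    The emission is constructed so that, with ``noise_rate = 0``, the
    phenotyping algorithms recover the latent case labels and incident ages
    exactly.  Noise events (isolated single dispensations and infant
    respiratory infections, given only to latent non-cases) can create
    wheeze false positives, making the wheeze phenotype deliberately less
    specific than the latent truth -- as in real register data.
    """
    config.validate()
    for outcome in ("wheeze", "asthma"):
        if outcome not in config.baseline_cuminc or outcome not in config.true_hr:
            raise InvalidConfigError(f"config must specify {outcome} hazard parameters")
    rng = _rng(config, 1)
    persons, latent = bundle.persons, bundle.latent.copy()
    n = len(persons)
    if n == 0:
        return bundle

    birth = pd.to_datetime(persons["birth_date"])
    admin_age = (pd.Timestamp(config.admin_end) - birth).dt.days.to_numpy().astype(float)
    cap3 = ((birth + pd.DateOffset(years=3)) - birth).dt.days.to_numpy().astype(float)
    cap12 = ((birth + pd.DateOffset(years=12)) - birth).dt.days.to_numpy().astype(float)
    group = latent["exposure_group"].to_numpy()

    # deaths and emigrations, uniform over the administrative window
    death_day = np.where(
        rng.random(n) < config.death_rate,
        np.ceil(rng.random(n) * admin_age), np.inf,
    )
    emig_day = np.where(
        rng.random(n) < config.emigration_rate,
        np.ceil(rng.random(n) * admin_age), np.inf,
    )
    emig_day = np.where(emig_day >= death_day, np.inf, emig_day)  # death wins ties
    exit0 = np.minimum.reduce([admin_age, death_day, emig_day])

    mult = _covariate_multiplier(latent, config.covariate_effects)
    if config.shared_frailty_sd > 0:
        mothers = persons["mother_id"].to_numpy()
        uniq, inv = np.unique(mothers, return_inverse=True)
        frailty = np.exp(rng.normal(0.0, config.shared_frailty_sd, size=len(uniq)))
        mult = mult * frailty[inv]

    hr_a = np.array([config.true_hr["asthma"].get(g, 1.0) for g in group])
    hr_w = np.array([config.true_hr["wheeze"].get(g, 1.0) for g in group])

    bg = group == "background"
    calib = bg if bg.any() else np.ones(n, dtype=bool)

    # ---- asthma latent onset ---------------------------------------------------
    h12 = np.minimum(cap12, exit0)
    hr_calib = np.ones(calib.sum()) if bg.any() else hr_a[calib]
    c_a = _solve_scale(
        config.baseline_cuminc["asthma"],
        mult[calib] * hr_calib,
        _cumhaz_shape(h12[calib]),
    )
    u = rng.random(n)
    total = -np.log(u) / np.maximum(c_a * hr_a * mult, 1e-300)
    a_day = np.maximum(np.ceil(_cumhaz_shape_inv(total)), 1.0)
    asthma_case = a_day < h12

    # persistence beyond 36 months (strict asthma)
    room_post36 = np.minimum(cap12, exit0) > cap3
    persist_draw = rng.random(n) < config.persistence_prob
    asthma3_case = asthma_case & (
        (a_day >= cap3) | (persist_draw & room_post36 & (a_day < cap3))
    )

    # ---- wheeze latent onset -----------------------------------------------------
    h3 = np.minimum(cap3, exit0)
    asthma_offset = c_a * mult[calib] * hr_calib * _cumhaz_shape(h3[calib])
    c_w = _solve_scale(
        config.baseline_cuminc["wheeze"],
        mult[calib] * (np.ones(calib.sum()) if bg.any() else hr_w[calib]),
        h3[calib],
        offset=asthma_offset,
    )
    u2 = rng.random(n)
    w_day = np.maximum(np.ceil(-np.log(u2) / np.maximum(c_w * hr_w * mult, 1e-300)), 1.0)
    asthma_in_window = asthma_case & (a_day < h3)
    wheeze_incident = np.where(
        asthma_in_window, np.minimum(w_day, a_day), w_day
    )
    wheeze_case = wheeze_incident < h3

    # ---- event emission ----------------------------------------------------------
    dx_pid, dx_day, dx_code, dx_src = [], [], [], []
    rx_pid, rx_day = [], []
    pid = persons["person_id"].to_numpy()

    def _dates(idx_pid, days):
        b = birth.set_axis(pid).loc[idx_pid].reset_index(drop=True)
        return (b + pd.to_timedelta(np.asarray(days, dtype=int), unit="D")).dt.strftime("%Y-%m-%d")

    if not emit_events:
        diagnoses = pd.DataFrame(columns=_DX_COLS)
        dispensations = pd.DataFrame(columns=_RX_COLS)

    case_idx = np.flatnonzero(asthma_case) if emit_events else np.empty(0, dtype=int)
    window_end = np.where(
        asthma_case & ~asthma3_case & (a_day < cap3),
        np.minimum(cap3, np.minimum(exit0, cap12)),
        np.minimum(exit0, cap12),
    )
    use_dx = rng.random(n) < config.dx_route_prob
    use_dx = use_dx | (window_end - a_day < 2)  # no room for a repeat
    delta = 30 + np.floor(rng.random(n) * 151)
    sources = np.array(["inpatient", "outpatient"])
    src_draw = sources[(rng.random(n) < 0.85).astype(int)]

    post_day = np.floor(
        cap3 + rng.random(n) * np.maximum(np.minimum(exit0, cap12) - cap3, 1.0)
    )
    post_day = np.minimum(post_day, np.minimum(exit0, cap12) - 1)

    for i in case_idx:
        a = a_day[i]
        if use_dx[i]:
            dx_pid.append(pid[i]); dx_day.append(a)
            dx_code.append("J45"); dx_src.append(src_draw[i])
        else:
            rep = min(a + delta[i], window_end[i] - 1)
            rx_pid.extend([pid[i], pid[i]]); rx_day.extend([a, rep])
        if asthma3_case[i] and a < cap3[i]:
            rx_pid.append(pid[i]); rx_day.append(max(post_day[i], cap3[i]))

    wheeze_codes = np.array(["J20", "J21", "J22"])
    wz_code = wheeze_codes[rng.integers(0, 3, size=n)]
    wheeze_emit = wheeze_case & (~asthma_in_window | (w_day < a_day)) & (w_day < h3)
    if not emit_events:
        wheeze_emit[:] = False
    for i in np.flatnonzero(wheeze_emit):
        dx_pid.append(pid[i]); dx_day.append(w_day[i])
        dx_code.append(wz_code[i]); dx_src.append("outpatient")

    # ---- noise for latent non-cases ----------------------------------------------
    clean = ~(asthma_case | wheeze_case)
    noisy = clean & (rng.random(n) < config.noise_rate) & (np.minimum(exit0, cap12) > 2)
    if not emit_events:
        noisy[:] = False
    kind_rx = rng.random(n) < 0.5
    noise_day_rx = np.maximum(np.floor(rng.random(n) * (np.minimum(exit0, cap12) - 1)), 1.0)
    noise_day_dx = np.maximum(np.floor(rng.random(n) * np.maximum(np.minimum(365.0, exit0) - 1, 1.0)), 1.0)
    for i in np.flatnonzero(noisy):
        if kind_rx[i]:
            rx_pid.append(pid[i]); rx_day.append(noise_day_rx[i])
        else:
            dx_pid.append(pid[i]); dx_day.append(noise_day_dx[i])
            dx_code.append(wz_code[i]); dx_src.append("outpatient")

    if emit_events:
        diagnoses = pd.DataFrame({
            "person_id": dx_pid,
            "event_date": _dates(dx_pid, dx_day) if dx_pid else pd.Series(dtype=str),
            "icd10_code": dx_code,
            "source": dx_src,
        })
        dispensations = pd.DataFrame({
            "person_id": rx_pid,
            "dispense_date": _dates(rx_pid, rx_day) if rx_pid else pd.Series(dtype=str),
            "atc_code": "R03",
        })

    # ---- parent events (drive the parental-asthma indicator) ----------------------
    par = bundle.parents
    window_start = pd.Timestamp("2006-01-01")
    window_days = (pd.Timestamp(config.admin_end) - window_start).days
    p_dx_pid, p_dx_day = [], []
    p_rx_pid, p_rx_day = [], []
    if not emit_events:
        par = par.iloc[0:0]
    par_case = par.loc[par["asthma_case"] == 1, "parent_id"].to_numpy()
    par_non = par.loc[par["asthma_case"] == 0, "parent_id"].to_numpy()
    p_route_dx = rng.random(len(par_case)) < 0.4
    d1 = np.floor(rng.random(len(par_case)) * (window_days - 400))
    gap = 30 + np.floor(rng.random(len(par_case)) * 300)
    for j, pid_ in enumerate(par_case):
        if p_route_dx[j]:
            p_dx_pid.append(pid_); p_dx_day.append(d1[j])
        else:
            p_rx_pid.extend([pid_, pid_]); p_rx_day.extend([d1[j], d1[j] + gap[j]])
    par_noise = par_non[rng.random(len(par_non)) < 0.10]
    nday = np.floor(rng.random(len(par_noise)) * window_days)
    p_rx_pid.extend(par_noise.tolist()); p_rx_day.extend(nday.tolist())

    def _pdates(days):
        return (window_start + pd.to_timedelta(np.asarray(days, dtype=int), unit="D")).strftime("%Y-%m-%d")

    if p_dx_pid:
        diagnoses = pd.concat([diagnoses, pd.DataFrame({
            "person_id": p_dx_pid, "event_date": _pdates(p_dx_day),
            "icd10_code": "J45", "source": "outpatient",
        })], ignore_index=True)
    if p_rx_pid:
        dispensations = pd.concat([dispensations, pd.DataFrame({
            "person_id": p_rx_pid, "dispense_date": _pdates(p_rx_day),
            "atc_code": "R03",
        })], ignore_index=True)

    # ---- vitals --------------------------------------------------------------------
    death_mask = np.isfinite(death_day)
    emig_mask = np.isfinite(emig_day) & ~death_mask
    v_pid = np.concatenate([pid[death_mask], pid[emig_mask]]).tolist()
    v_day = np.concatenate([death_day[death_mask], emig_day[emig_mask]])
    vitals = pd.DataFrame({
        "person_id": v_pid,
        "event_date": _dates(v_pid, v_day) if v_pid else pd.Series(dtype=str),
        "kind": ["death"] * int(death_mask.sum()) + ["emigration"] * int(emig_mask.sum()),
    })

    latent["asthma_case"] = asthma_case.astype(int)
    latent["asthma_incident_day"] = np.where(asthma_case, a_day, np.nan)
    latent["asthma_3plus_case"] = asthma3_case.astype(int)
    latent["asthma_3plus_incident_day"] = np.where(asthma3_case, a_day, np.nan)
    latent["wheeze_case"] = wheeze_case.astype(int)
    latent["wheeze_incident_day"] = np.where(wheeze_case, wheeze_incident, np.nan)
    latent["death_day"] = np.where(np.isfinite(death_day), death_day, np.nan)
    latent["emigration_day"] = np.where(np.isfinite(emig_day), emig_day, np.nan)
    latent["admin_age_days"] = admin_age
    latent["cap3_days"] = cap3
    latent["cap12_days"] = cap12

    return RegisterBundle(
        persons=persons, addresses=bundle.addresses,
        diagnoses=diagnoses, dispensations=dispensations, vitals=vitals,
        latent=latent, parents=bundle.parents, config=config,
    )


def generate_biomarker_cohort(
    config: SimConfig,
    n_per_group: Optional[dict] = None,
    sigma_scale: float = 1.0,
    sampling_years: tuple = (2014, 2016),
) -> pd.DataFrame:
    """Serum PFAS samples per exposure category, lognormal per analyte.

    Medians and IQR spreads default to the biomarker-validation calibration
    table; ``sigma_scale=0`` collapses each distribution to its median.
    """
    config.validate()
    if sigma_scale < 0:
        raise InvalidConfigError("sigma_scale must be >= 0")
    rng = _rng(config, 2)
    n_per_group = dict(BIOMARKER_GROUP_N if n_per_group is None else n_per_group)
    if any(v < 0 for v in n_per_group.values()):
        raise InvalidConfigError("n_per_group must be nonnegative")

    z75 = 0.6744897501960817  # standard normal 75th percentile
    rows = []
    counter = 0
    for glabel in GROUP_LABELS:
        k = int(n_per_group.get(glabel, 0))
        if k == 0:
            continue
        sample = {"person_id": [f"B{counter + i:05d}" for i in range(k)],
                  "exposure_group": [glabel] * k,
                  "sampling_year": rng.integers(sampling_years[0], sampling_years[1] + 1, size=k)}
        counter += k
        for analyte, table in BIOMARKER_CALIBRATION.items():
            med, q1, q3 = table[glabel]
            if med <= 0 or q1 <= 0 or q3 <= 0:
                raise InvalidConfigError("biomarker scale parameters must be positive")
            sigma = sigma_scale * np.log(q3 / q1) / (2.0 * z75)
            sample[analyte] = np.exp(rng.normal(np.log(med), sigma, size=k)) if sigma > 0 \
                else np.full(k, float(med))
        rows.append(pd.DataFrame(sample))
    if not rows:
        return pd.DataFrame(columns=["person_id", "exposure_group", "sampling_year",
                                     *BIOMARKER_CALIBRATION.keys()])
    return pd.concat(rows, ignore_index=True)


def generate_bundle(config: SimConfig, emit_events: bool = True) -> RegisterBundle:
    """Population + health events in one call."""
    return generate_health_events(generate_population(config), config, emit_events=emit_events)


def latent_followups(bundle: RegisterBundle, outcome: str) -> pd.DataFrame:
    """Open-cohort follow-up records taken directly from the latent truth.

    Fast path for simulation studies: identical to building follow-up from
    the emitted event streams via phenotyping when noise is disabled (the
    generator/phenotyper contract), without materialising the events.
    """
    if outcome not in ("wheeze", "asthma", "asthma_3plus"):
        raise ValueError(f"unknown outcome {outcome!r}")
    lat = bundle.latent
    cap = lat["cap3_days"] if outcome == "wheeze" else lat["cap12_days"]
    cap = cap.to_numpy(dtype=float)
    incident = lat[f"{outcome}_incident_day"].to_numpy(dtype=float)
    death = lat["death_day"].fillna(np.inf).to_numpy(dtype=float)
    emig = lat["emigration_day"].fillna(np.inf).to_numpy(dtype=float)
    # administrative follow-up runs through the closing date inclusive
    admin = lat["admin_age_days"].to_numpy(dtype=float) + 1.0

    candidates = np.column_stack([
        np.where(np.isnan(incident), np.inf, incident), death, emig, cap, admin,
    ])
    reason_labels = np.array(["event", "death", "emigration", "age_cap", "admin_end"])
    which = np.argmin(candidates, axis=1)  # argmin honours the tie precedence
    exit_days = candidates[np.arange(len(lat)), which]
    return pd.DataFrame({
        "person_id": lat["person_id"].to_numpy(),
        "cluster_id": bundle.persons["mother_id"].to_numpy(),
        "outcome": outcome,
        "entry_age_days": 0,
        "exit_age_days": exit_days.astype(int),
        "event": (which == 0).astype(int),
        "censor_reason": reason_labels[which],
        "exposure": lat["exposure_group"].to_numpy(),
    })
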