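"""Survival estimation: KM oracle, Cox partial-likelihood oracle, Wald tests,
proportional-hazards diagnostics, sex interaction."""

import numpy as np
import pandas as pd
import pytest
from lifelines.statistics import logrank_test
from scipy.optimize import minimize
from scipy.stats import chi2

from pfascohort import (
    SimConfig,
    WaldTestResult,
    add_exposure_dummies,
    cox_fit,
    derive_covariates,
    generate_bundle,
    interaction_wald,
    km_cumulative_incidence_at,
    km_curve,
    latent_followups,
    ph_diagnostics,
    wald_joint,
)


def fu_frame(times, events, **cols):
    df = pd.DataFrame({"exit_age_days": times, "event": events})
    df["cluster_id"] = cols.pop("cluster_id", np.arange(len(df)))
    for k, v in cols.items():
        df[k] = v
    return df


# --- Kaplan-Meier -------------------------------------------------------------

def test_km_matches_hand_product_limit():
    """Events at t=1,2 with censorings at 1.5, 3: 1 - (3/4)(1/2) = 0.625."""
    df = fu_frame([1.0, 1.5, 2.0, 3.0], [1, 0, 1, 0])
    curve = km_curve(df)["all"]
    assert curve.cum_incidence_at(2.0) == pytest.approx(0.625)
    assert km_cumulative_incidence_at(df["exit_age_days"], df["event"], 2.0) == pytest.approx(0.625)


def test_km_degenerate_cases():
    all_censored = fu_frame([1, 2, 3], [0, 0, 0])
    assert km_curve(all_censored)["all"].cum_incidence_at(3) == 0.0
    assert km_cumulative_incidence_at([1, 2, 3], [0, 0, 0], 3) == 0.0
    one_time = fu_frame([2, 2, 2], [1, 1, 1])
    assert km_curve(one_time)["all"].cum_incidence_at(2) == pytest.approx(1.0)
    assert km_cumulative_incidence_at([2, 2, 2], [1, 1, 1], 2) == pytest.approx(1.0)


def test_fast_km_agrees_with_lifelines_on_random_data(rng):
    for _ in range(20):
        n = rng.integers(5, 60)
        t = rng.integers(1, 40, size=n).astype(float)
        e = rng.random(n) < 0.5
        horizon = float(rng.integers(1, 45))
        df = fu_frame(t, e.astype(int))
        expected = km_curve(df)["all"].cum_incidence_at(horizon)
        assert km_cumulative_incidence_at(t, e, horizon) == pytest.approx(expected)


def test_negative_times_rejected():
    with pytest.raises(ValueError):
        km_curve(fu_frame([-1, 2], [1, 0]))


# --- Cox oracle ----------------------------------------------------------------

def breslow_neg_loglik(beta, times, events, x):
    """Direct partial likelihood (no ties in the fixture, so Breslow = Efron)."""
    ll = 0.0
    eta = x @ beta
    for i in np.flatnonzero(events):
        risk = times >= times[i]
        ll += eta[i] - np.log(np.sum(np.exp(eta[risk])))
    return -ll


def test_cox_matches_direct_partial_likelihood_maximisation():
    times = np.array([3.0, 5.0, 7.0, 11.0, 13.0, 17.0])
    events = np.array([1, 1, 0, 1, 1, 0])
    x = np.array([[1.0], [0.0], [1.0], [0.0], [1.0], [0.0]])
    df = fu_frame(times, events, covar=x[:, 0], sexless=0)
    res = cox_fit(df, covariates=["covar"], strata=(), include_exposure=False)
    direct = minimize(
        breslow_neg_loglik, np.zeros(1), args=(times, events, x), method="BFGS", tol=1e-12
    )
    assert res.params["covar"] == pytest.approx(direct.x[0], abs=1e-6)


def test_constant_covariate_is_inestimable():
    df = fu_frame([1, 2, 3, 4], [1, 1, 0, 1], covar=1.0)
    with pytest.raises(ValueError, match="constant"):
        cox_fit(df, covariates=["covar"], strata=(), include_exposure=False)


def test_singleton_clusters_reproduce_unclustered_robust_variance():
    rng = np.random.default_rng(5)
    n = 120
    df = fu_frame(
        rng.exponential(10, n) + 0.1,  # tie-free
        (rng.random(n) < 0.7).astype(int),
        covar=rng.standard_normal(n),
    )
    clustered = cox_fit(df, covariates=["covar"], strata=(), include_exposure=False)
    from lifelines import CoxPHFitter

    plain = CoxPHFitter()
    plain.fit(df[["exit_age_days", "event", "covar"]], "exit_age_days", "event", robust=True)
    assert np.sqrt(clustered.covariance.loc["covar", "covar"]) == pytest.approx(
        plain.standard_errors_["covar"], rel=1e-6
    )


def test_score_test_at_null_equals_logrank():
    """Two groups, no ties: the Cox score test at beta=0 is the log-rank test."""
    rng = np.random.default_rng(7)
    n = 40
    t = np.sort(rng.exponential(10, n)) + rng.random(n) * 1e-3
    e = (rng.random(n) < 0.8).astype(int)
    g = (rng.random(n) < 0.5).astype(float)
    # score U(0) and information I(0) from the partial likelihood, by hand
    U = 0.0
    I = 0.0
    for i in np.flatnonzero(e):
        risk = t >= t[i]
        xbar = g[risk].mean()
        U += g[i] - xbar
        I += xbar * (1 - xbar)
    score_chi2 = U**2 / I
    lr = logrank_test(t[g == 1], t[g == 0], e[g == 1], e[g == 0])
    assert score_chi2 == pytest.approx(lr.test_statistic, rel=1e-9)


# --- Wald tests -----------------------------------------------------------------

def test_wald_closed_form():
    params = pd.Series({"b": 2.0})
    cov = pd.DataFrame({"b": [1.0]}, index=["b"])
    res = wald_joint(params, cov, ["b"])
    assert res.statistic == pytest.approx(4.0)
    assert res.p_value == pytest.approx(chi2.sf(4.0, 1))
    null = wald_joint(pd.Series({"b": 0.0}), cov, ["b"])
    assert null.statistic == 0.0 and null.p_value == 1.0


# --- diagnostics and interaction --------------------------------------------------

def _cohort_followups(seed=2, n=2500, **cfg_kw):
    cfg = SimConfig(n_children=n, seed=seed, noise_rate=0.0, missing_rate={}, **cfg_kw)
    bundle = generate_bundle(cfg)
    fu = latent_followups(bundle, "asthma")
    lat = bundle.latent.set_index("person_id")
    cov = derive_covariates(bundle.persons, lat["parental_asthma"].astype(bool))
    return add_exposure_dummies(fu.merge(cov, on="person_id"))


def test_ph_diagnostics_returns_tests_under_ph():
    df = _cohort_followups()
    res = cox_fit(df, covariates=["smoking"], strata=("sex", "parity"))
    schoenfeld, joint = ph_diagnostics(res, df, covariates=["smoking"])
    assert {"covariate", "p"} <= set(schoenfeld.columns)
    assert isinstance(joint, WaldTestResult)
    assert 0.0 <= joint.p_value <= 1.0


def test_sex_interaction_zero_on_sex_symmetric_data():
    """Duplicating every child with flipped sex forces interaction terms to 0."""
    df = _cohort_followups(n=1200)
    flipped = df.copy()
    flipped["sex"] = 1.0 - flipped["sex"]
    flipped["cluster_id"] = flipped["cluster_id"] + "_flip"
    sym = pd.concat([df, flipped], ignore_index=True)
    joint, per_sex = interaction_wald(sym, covariates=())
    hr_f = per_sex[1.0].summary.loc["exp_very_high", "hr"]
    hr_m = per_sex[0.0].summary.loc["exp_very_high", "hr"]
    assert hr_f == pytest.approx(hr_m, rel=1e-6)
    assert joint.statistic == pytest.approx(0.0, abs=1e-8)


def test_strong_qualitative_interaction_splits_stratified_hrs(rng):
    """Construct opposite effects by sex; stratified HRs land on opposite sides of 1."""
    n = 4000
    sex = (rng.random(n) < 0.5).astype(float)
    vh = (rng.random(n) < 0.3).astype(float)
    log_hr = np.where(sex == 1, -0.9, 0.9) * vh
    t = rng.exponential(100 / np.exp(log_hr))
    c = rng.uniform(20, 200, n)
    df = fu_frame(
        np.minimum(t, c).round(3) + 0.001, (t <= c).astype(int),
        sex=sex, parity=0.0, exposure=np.where(vh == 1, "very_high", "background"),
    )
    df = add_exposure_dummies(df)
    df = df.drop(columns=["exp_intermediate", "exp_high"])
    df["exp_intermediate"] = 0.0
    df["exp_high"] = 0.0
    joint, per_sex = interaction_wald(df, covariates=(), strata=("sex",))
    hr_g = per_sex[1.0].summary.loc["exp_very_high", "hr"]
    hr_b = per_sex[0.0].summary.loc["exp_very_high", "hr"]
    assert (hr_g - 1) * (hr_b - 1) < 0
    assert joint.p_value < 1e-6
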