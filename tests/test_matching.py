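"""Rank-Mahalanobis matching, balance, KM-difference statistic, Fisher test."""

import numpy as np
import pandas as pd
import pytest

from pfascohort import (
    MatchedSet,
    covariate_balance,
    fisher_randomization_test,
    greedy_nn_match,
    km_difference_statistic,
    match_cohort,
    rank_mahalanobis_distance,
)
from pfascohort.matching import InsufficientControlsError


# --- distances -----------------------------------------------------------------

def test_identical_rows_have_zero_distance():
    x = np.array([[1.0, 2.0], [3.0, 4.0]])
    d = rank_mahalanobis_distance(x, x)
    assert d[0, 0] == pytest.approx(0.0) and d[1, 1] == pytest.approx(0.0)


def test_single_covariate_no_ties_is_squared_rank_difference():
    """With one tie-free covariate the metric reduces to squared rank
    differences over the untied-rank variance (hand formula)."""
    t = np.array([[1.0], [10.0]])
    c = np.array([[2.0], [5.0], [20.0]])
    d = rank_mahalanobis_distance(t, c)
    pooled = np.concatenate([t[:, 0], c[:, 0]])
    ranks = pooled.argsort().argsort() + 1.0
    var = (len(pooled) ** 2 - 1) / 12.0
    expected = (ranks[:2][:, None] - ranks[2:][None, :]) ** 2 / var
    np.testing.assert_allclose(d, expected, rtol=1e-9)


def test_monotone_transform_invariance(rng):
    t = rng.normal(size=(5, 3))
    c = rng.normal(size=(12, 3))
    d1 = rank_mahalanobis_distance(t, c)
    t2, c2 = t.copy(), c.copy()
    t2[:, 1] = np.exp(t2[:, 1])
    c2[:, 1] = np.exp(c2[:, 1])
    np.testing.assert_allclose(d1, rank_mahalanobis_distance(t2, c2), rtol=1e-9)


def test_singular_covariance_warns_and_regularises():
    t = np.array([[1.0, 2.0]])
    c = np.array([[2.0, 4.0], [3.0, 6.0], [4.0, 8.0]])  # perfectly collinear
    with pytest.warns(UserWarning, match="singular"):
        d = rank_mahalanobis_distance(t, c)
    assert np.isfinite(d).all()


# --- greedy matching --------------------------------------------------------------

def test_exactly_three_controls_all_matched():
    d = np.array([[3.0, 1.0, 2.0]])
    sets = greedy_nn_match(d, ratio=3)
    assert sets == [(0, (1, 2, 0))]


def test_insufficient_controls_names_shortfall():
    with pytest.raises(InsufficientControlsError, match="need 6"):
        greedy_nn_match(np.zeros((2, 5)), ratio=3)


def test_matching_is_deterministic_with_index_tie_break(rng):
    d = rng.integers(0, 4, size=(6, 30)).astype(float)  # many ties
    assert greedy_nn_match(d) == greedy_nn_match(d.copy())
    # all-equal distances: ties broken by control input index
    flat = np.ones((2, 6))
    assert greedy_nn_match(flat) == [(0, (0, 1, 2)), (1, (3, 4, 5))]


def test_rank_monotonicity_single_covariate(rng):
    """Matching on a tie-free covariate depends only on the value order:
    replacing values by their midranks leaves every matched set unchanged."""
    from scipy.stats import rankdata

    t = pd.DataFrame({"person_id": ["t0", "t1"], "x": [0.3, 0.9]})
    c = pd.DataFrame({"person_id": [f"c{i}" for i in range(8)],
                      "x": [0.1, 0.35, 0.32, 2.0, 0.95, 0.85, 0.7, 3.0]})
    pooled = rankdata(np.concatenate([t["x"], c["x"]]))
    t_r = t.assign(x=pooled[:2])
    c_r = c.assign(x=pooled[2:])
    assert match_cohort(t, c, ["x"], ratio=3) == match_cohort(t_r, c_r, ["x"], ratio=3)


# --- balance ----------------------------------------------------------------------

def test_smd_direct_formula():
    t = pd.DataFrame({"z": [1.0] * 6 + [0.0] * 4})     # mean 0.6
    c = pd.DataFrame({"z": [1.0] * 4 + [0.0] * 6})     # mean 0.4
    rows = covariate_balance(t, c, c, ["z"])
    pooled_sd = np.sqrt((t["z"].var() + c["z"].var()) / 2)
    assert rows[0].smd_before == pytest.approx(0.2 / pooled_sd)
    identical = covariate_balance(t, t, t, ["z"])
    assert identical[0].smd_before == pytest.approx(0.0)


def test_zero_pooled_sd_flags_undefined():
    t = pd.DataFrame({"z": [1.0, 1.0]})
    with pytest.warns(UserWarning, match="SMD undefined"):
        rows = covariate_balance(t, t, t, ["z"])
    assert np.isnan(rows[0].smd_before)


def test_matching_improves_balance_on_confounded_data(rng):
    n_t, n_c = 60, 600
    xt = rng.normal(1.0, 1.0, size=(n_t, 2))
    xc = rng.normal(0.0, 1.0, size=(n_c, 2))
    t = pd.DataFrame(xt, columns=["a", "b"]).assign(person_id=[f"t{i}" for i in range(n_t)])
    c = pd.DataFrame(xc, columns=["a", "b"]).assign(person_id=[f"c{i}" for i in range(n_c)])
    sets = match_cohort(t, c, ["a", "b"])
    matched = c[c["person_id"].isin({cid for s in sets for cid in s.control_ids})]
    rows = covariate_balance(t, c, matched, ["a", "b"])
    assert max(abs(r.smd_after) for r in rows) < max(abs(r.smd_before) for r in rows)


# --- randomization inference -------------------------------------------------------

def make_sets(times, events):
    """times/events: (S, 4) arrays; member 0 is the treated child."""
    S = len(times)
    fu = pd.DataFrame({
        "person_id": [f"p{k}_{j}" for k in range(S) for j in range(4)],
        "exit_age_days": np.asarray(times).ravel(),
        "event": np.asarray(events).ravel().astype(int),
    })
    sets = [
        MatchedSet(k, f"p{k}_0", (f"p{k}_1", f"p{k}_2", f"p{k}_3")) for k in range(S)
    ]
    return sets, fu


def test_km_difference_hand_computed():
    # treated: events at 1, 2 of 2 -> cuminc 1; controls: 1 event of 2 at t=1
    t_obs = km_difference_statistic(
        np.array([1.0, 2.0]), np.array([True, True]),
        np.array([1.0, 3.0]), np.array([True, False]), horizon=3.0,
    )
    assert t_obs == pytest.approx(100.0 * (1.0 - 0.5))
    assert km_difference_statistic(
        np.array([1.0]), np.array([False]), np.array([1.0]), np.array([False]), 2.0
    ) == 0.0


def test_no_events_give_p_one():
    sets, fu = make_sets(np.full((3, 4), 10.0), np.zeros((3, 4)))
    res = fisher_randomization_test(sets, fu, horizon=12.0, n_perm=100, seed=0)
    assert res.t_obs == 0.0 and res.p_value == 1.0


def test_sampled_p_converges_to_enumeration(rng):
    times = rng.uniform(1, 10, size=(2, 4))
    events = rng.random((2, 4)) < 0.6
    sets, fu = make_sets(times, events)
    exact = fisher_randomization_test(sets, fu, horizon=10.0, n_perm=10, seed=0)
    assert exact.exact and exact.n_perm == 16
    sampled = fisher_randomization_test(
        sets, fu, horizon=10.0, n_perm=20000, seed=1, enumerate_threshold=0
    )
    se = np.sqrt(exact.p_value * (1 - exact.p_value) / 20000)
    assert abs(sampled.p_value - exact.p_value) < 3 * se + 2 / 20000


def test_p_invariant_to_set_relabelling_and_control_order(rng):
    times = rng.uniform(1, 10, size=(5, 4))
    events = rng.random((5, 4)) < 0.5
    sets, fu = make_sets(times, events)
    base = fisher_randomization_test(sets, fu, horizon=10.0, n_perm=10, seed=0)
    shuffled = [
        MatchedSet(9 - s.set_index, s.treated_id, s.control_ids[::-1]) for s in sets[::-1]
    ]
    again = fisher_randomization_test(shuffled, fu, horizon=10.0, n_perm=10, seed=0)
    assert base.p_value == pytest.approx(again.p_value)
    assert base.t_obs == pytest.approx(again.t_obs)


def test_observed_assignment_in_support(rng):
    times = rng.uniform(1, 10, size=(4, 4))
    events = rng.random((4, 4)) < 0.7
    sets, fu = make_sets(times, events)
    res = fisher_randomization_test(sets, fu, horizon=10.0, n_perm=50, seed=2)
    assert res.p_value >= 1.0 / (1 + res.n_perm)


def test_n_perm_validation(rng):
    sets, fu = make_sets(np.ones((2, 4)), np.zeros((2, 4)))
    with pytest.raises(ValueError):
        fisher_randomization_test(sets, fu, horizon=2.0, n_perm=0)
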