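"""Survival statistics against hand-computed, brute-force and reference oracles."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps
from scipy.optimize import minimize

from wsisurv.survstats import (CoxFit, KMCurve, LandmarkSpec, cox_fit, dfs_at,
                               km_fit, landmark_filter, logrank)
from wsisurv.training import SurvivalLabel


def L(items):
    return [SurvivalLabel(f"p{i}", float(t), int(e)) for i, (t, e) in enumerate(items)]


# -- Kaplan-Meier -------------------------------------------------------------

def test_km_hand_product_limit():
    curve = km_fit(L([(1, 1), (2, 0), (3, 1)]))
    # S(1) = 1 - 1/3 = 2/3; censoring at 2 removes one at risk; S(3) = 0
    np.testing.assert_allclose(curve.event_times, [1.0, 3.0])
    np.testing.assert_allclose(curve.survival, [2 / 3, 0.0])
    assert curve.n == 3 and curve.n_events == 2


def test_km_no_events_is_flat_one():
    curve = km_fit(L([(1, 0), (5, 0)]))
    assert curve.event_times.size == 0
    assert dfs_at(curve, 3.0)[0] == 1.0


def test_km_without_censoring_is_one_minus_ecdf():
    times = [1.0, 2.5, 4.0, 7.0]
    curve = km_fit(L([(t, 1) for t in times]))
    for t in (0.5, 1.5, 3.0, 5.0, 7.0):
        expected = np.mean([x > t for x in times])
        assert dfs_at(curve, t)[0] == pytest.approx(expected)


def test_censored_at_event_time_stays_at_risk():
    # subject censored exactly at the event time counts in the risk set
    curve = km_fit(L([(2, 1), (2, 0), (4, 1)]))
    np.testing.assert_allclose(curve.survival[0], 1 - 1 / 3)


def test_dfs_at_step_evaluation_and_extrapolation():
    curve = km_fit(L([(1, 1), (2, 0), (3, 1)]))
    assert dfs_at(curve, 0.0) == (1.0, False)
    assert dfs_at(curve, 0.5) == (1.0, False)
    assert dfs_at(curve, 2.5)[0] == pytest.approx(2 / 3)
    value, extrapolated = dfs_at(curve, 10.0)
    assert extrapolated and value == pytest.approx(0.0)


def test_km_survival_must_be_nonincreasing():
    with pytest.raises(ValueError):
        KMCurve(np.array([1.0, 2.0]), np.array([0.5, 0.8]), np.array([3, 2]),
                n=3, n_events=2, max_observed=2.0)


# -- log-rank -----------------------------------------------------------------

def _mantel_cox_oracle(times, events, group):
    """Observed-minus-expected 2-group table per event time, by hand."""
    o_minus_e = 0.0
    var = 0.0
    for t in sorted(set(times[events == 1])):
        at_risk = times >= t
        n = at_risk.sum()
        n1 = (at_risk & (group == 1)).sum()
        d = ((times == t) & (events == 1)).sum()
        d1 = ((times == t) & (events == 1) & (group == 1)).sum()
        o_minus_e += d1 - d * n1 / n
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    return o_minus_e ** 2 / var


def test_identical_groups_give_null_statistic():
    g = L([(1, 1), (2, 0), (3, 1)])
    chi2, p = logrank({"a": g, "b": list(g)})
    assert chi2 == pytest.approx(0.0, abs=1e-12)
    assert p == pytest.approx(1.0)


def test_logrank_matches_hand_table_on_six_subjects():
    ga = L([(1, 1), (4, 1), (6, 0)])
    gb = L([(2, 1), (5, 0), (7, 1)])
    chi2, p = logrank({"a": ga, "b": gb})
    times = np.array([1, 4, 6, 2, 5, 7], float)
    events = np.array([1, 1, 0, 1, 0, 1])
    group = np.array([0, 0, 0, 1, 1, 1])
    expected = _mantel_cox_oracle(times, events, group)
    assert chi2 == pytest.approx(expected, rel=1e-10)
    assert p == pytest.approx(sps.chi2.sf(expected, 1), rel=1e-10)


def test_logrank_p_consistent_with_permutation_oracle():
    r = np.random.default_rng(11)
    times = r.uniform(1, 10, 20)
    events = (r.random(20) < 0.8).astype(int)
    group = np.array([0] * 10 + [1] * 10)
    labels = {g: [SurvivalLabel(f"p{i}", times[i], events[i])
                  for i in range(20) if group[i] == g] for g in (0, 1)}
    _, p = logrank(labels)
    observed = _mantel_cox_oracle(times, events, group)
    hits = 0
    n_perm = 10_000
    for _ in range(n_perm):
        gp = r.permutation(group)
        hits += _mantel_cox_oracle(times, events, gp) >= observed - 1e-12
    p_perm = hits / n_perm
    # Monte-Carlo 99% band around the permutation estimate
    se = np.sqrt(p_perm * (1 - p_perm) / n_perm)
    assert abs(p - p_perm) < max(3 * se, 0.02)


def test_logrank_invariant_to_monotone_time_transform():
    ga = L([(1, 1), (4, 1), (6, 0)])
    gb = L([(2, 1), (5, 0), (7, 1)])
    chi2_a, _ = logrank({"a": ga, "b": gb})
    sq = lambda ls: [SurvivalLabel(l.patient_id, l.time_months ** 2, l.event) for l in ls]
    chi2_b, _ = logrank({"a": sq(ga), "b": sq(gb)})
    assert chi2_a == pytest.approx(chi2_b, rel=1e-10)


def test_logrank_rejects_empty_group():
    with pytest.raises(ValueError):
        logrank({"a": L([(1, 1)]), "b": []})


# -- Cox ----------------------------------------------------------------------

def _breslow_loglik_oracle(beta, times, events, x):
    ll = 0.0
    for i in np.where(events == 1)[0]:
        risk = times >= times[i]
        ll += x[i] @ beta - np.log(np.sum(np.exp(x[risk] @ beta)))
    return ll


def test_cox_agrees_with_direct_likelihood_maximization():
    # independent route: scipy maximizes the same closed-form likelihood
    r = np.random.default_rng(1)
    worst = 0.0
    for _ in range(50):
        n = int(r.integers(15, 25))
        x = r.normal(size=(n, 2))
        te = r.exponential(1 / (0.1 * np.exp(x @ [0.7, -0.4])))
        tc = r.exponential(12, n)
        t = np.minimum(te, tc)
        e = (te <= tc).astype(int)
        if e.sum() < 4:
            continue
        labels = [SurvivalLabel(f"p{i}", t[i], e[i]) for i in range(n)]
        fit = cox_fit(labels, x)
        res = minimize(lambda b: -_breslow_loglik_oracle(b, t, e, x), np.zeros(2),
                       method="BFGS", options={"gtol": 1e-12})
        if np.abs(res.x).max() < 10:  # skip near-separation draws
            worst = max(worst, np.abs(np.exp(fit.coef) - np.exp(res.x)).max()
                        / np.abs(np.exp(res.x)).max())
    assert worst < 1e-6


def test_cox_agrees_with_lifelines_on_tie_free_data():
    from lifelines import CoxPHFitter

    r = np.random.default_rng(2)
    for _ in range(10):
        n = 60
        x = r.normal(size=(n, 2))
        te = r.exponential(1 / (0.1 * np.exp(x @ [0.8, -0.5])))
        tc = r.exponential(15, n)
        t = np.minimum(te, tc)
        e = (te <= tc).astype(int)
        labels = [SurvivalLabel(f"p{i}", t[i], e[i]) for i in range(n)]
        fit = cox_fit(labels, x, names=["a", "b"])
        df = pd.DataFrame(x, columns=["a", "b"])
        df["T"], df["E"] = t, e
        cph = CoxPHFitter().fit(df, "T", "E")
        np.testing.assert_allclose(fit.coef, cph.params_.values, rtol=1e-4)
        np.testing.assert_allclose(fit.se, cph.standard_errors_.values, rtol=1e-4)


def test_cox_refuses_constant_covariate():
    labels = L([(1, 1), (2, 1), (3, 1), (4, 1)])
    with pytest.raises(ValueError, match="variation"):
        cox_fit(labels, np.ones(4))


def test_cox_refuses_more_covariates_than_events():
    labels = L([(1, 1), (2, 0), (3, 0), (4, 0)])
    with pytest.raises(ValueError):
        cox_fit(labels, np.random.default_rng(0).normal(size=(4, 2)))


def test_cox_flags_separation():
    # perfectly ordered groups: monotone likelihood
    labels = L([(1, 1), (2, 1), (3, 1), (10, 1), (11, 1), (12, 1)])
    x = np.array([1, 1, 1, 0, 0, 0], float)
    fit = cox_fit(labels, x)
    assert any("separation" in f for f in fit.flags)
    assert np.abs(fit.coef).max() <= 20


def test_cox_hr_invariant_to_time_shift():
    r = np.random.default_rng(3)
    x = (r.random(50) < 0.5).astype(float)
    te = r.exponential(1 / (0.1 * np.exp(0.7 * x)))
    labels = [SurvivalLabel(f"p{i}", te[i], 1) for i in range(50)]
    shifted = [SurvivalLabel(l.patient_id, l.time_months + 100.0, l.event)
               for l in labels]
    f1 = cox_fit(labels, x)
    f2 = cox_fit(shifted, x)
    assert f1.hr[0] == pytest.approx(f2.hr[0], rel=1e-8)


def test_cox_efron_flag_delegates():
    r = np.random.default_rng(4)
    x = r.normal(size=40)
    te = r.exponential(1 / (0.1 * np.exp(0.5 * x)))
    labels = [SurvivalLabel(f"p{i}", te[i], 1) for i in range(40)]
    fb = cox_fit(labels, x, ties="breslow")
    fe = cox_fit(labels, x, ties="efron")
    # tie-free data: both estimators target the same likelihood
    assert fb.hr[0] == pytest.approx(fe.hr[0], rel=1e-3)


# -- landmark -----------------------------------------------------------------

def test_landmark_zero_is_identity():
    labels = L([(2, 1), (4, 1), (5, 0)])
    out = landmark_filter(labels, LandmarkSpec(0.0))
    assert [(l.time_months, l.event) for l in out] == [(2, 1), (4, 1), (5, 0)]


def test_landmark_drops_and_reorigins():
    out = landmark_filter(L([(2, 1), (4, 1), (5, 0)]), LandmarkSpec(3.0))
    assert [(l.time_months, l.event) for l in out] == [(1.0, 1), (2.0, 0)]


def test_landmark_matches_conditional_survival_identity():
    # no censoring before the landmark: KM of re-origined data at t equals
    # S(t + L) / S(L) from the unfiltered fit
    r = np.random.default_rng(5)
    times = r.exponential(10, 60) + 0.01
    labels = [SurvivalLabel(f"p{i}", times[i], 1) for i in range(60)]
    L0 = 4.0
    full = km_fit(labels)
    cond = km_fit(landmark_filter(labels, LandmarkSpec(L0)))
    for t in (1.0, 3.0, 6.0):
        s_cond = dfs_at(cond, t)[0]
        s_ratio = dfs_at(full, t + L0)[0] / dfs_at(full, L0)[0]
        assert s_cond == pytest.approx(s_ratio, abs=1e-12)


def test_landmark_excluding_everyone_is_an_error():
    with pytest.raises(ValueError):
        landmark_filter(L([(1, 1), (2, 1)]), LandmarkSpec(5.0))
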