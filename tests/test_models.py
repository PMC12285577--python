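"""Regression contracts: oracles, baselines, grids, absolute risk."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from gxlife import SimulationConfig, generate_cohort
from gxlife.genetics import attach_genetic_risk
from gxlife.models import (CoxModel, absolute_risk_by_age, fit_cox,
                           fit_logistic, fit_risk_model, isolated_effect,
                           joint_category_grid, risk_gradient_curve)

# -- Cox oracle -------------------------------------------------------------

def _toy3():
    return pd.DataFrame({"time": [1.0, 2.0, 3.0], "event": [1.0, 1.0, 0.0],
                         "x": [0.0, 1.0, 0.0]})


def _partial_loglik_3subject(beta):
    """Breslow partial log-likelihood for the 3-subject toy, by enumeration."""
    u = np.exp(beta)
    # event at t=1 (x=0), risk set {all}; event at t=2 (x=1), risk set {2,3}
    return -np.log(2.0 + u) + beta - np.log(1.0 + u)


def test_cox_matches_brute_force_grid_search():
    grid = np.linspace(-5, 5, 20001)
    oracle = grid[np.argmax(_partial_loglik_3subject(grid))]
    # closed form for this toy: exp(beta) = sqrt(2)
    assert oracle == pytest.approx(np.log(np.sqrt(2.0)), abs=1e-3)
    res = fit_cox(_toy3(), "time", "event", ["x"])
    assert res.params["x"] == pytest.approx(oracle, abs=1e-3)


def test_cox_agrees_with_lifelines_on_tie_free_data():
    """Independent engine cross-check (Breslow == Efron without ties)."""
    from lifelines import CoxPHFitter

    rng = np.random.default_rng(2)
    n = 800
    x1 = rng.normal(size=n)
    x2 = rng.binomial(1, 0.4, n).astype(float)
    t = rng.exponential(1.0, n) / np.exp(0.5 * x1 - 0.3 * x2)
    event = (t <= 2.0).astype(float)
    df = pd.DataFrame({"time": np.minimum(t, 2.0), "event": event,
                       "x1": x1, "x2": x2})
    events = df["event"] == 1  # tie-free event times (censoring ties are fine)
    assert df.loc[events, "time"].nunique() == int(events.sum())
    ours = fit_cox(df, "time", "event", ["x1", "x2"])
    cph = CoxPHFitter().fit(df, duration_col="time", event_col="event")
    np.testing.assert_allclose(ours.params[["x1", "x2"]],
                               cph.params_[["x1", "x2"]], atol=1e-4)
    np.testing.assert_allclose(ours.se[["x1", "x2"]],
                               cph.standard_errors_[["x1", "x2"]], atol=1e-4)


def test_cox_constant_covariate_pinned_at_zero():
    df = _toy3()
    df["z"] = 0.0
    res = fit_cox(df, "time", "event", ["x", "z"])
    assert res.params["z"] == 0.0
    assert np.exp(res.params["z"]) == 1.0
    assert "z" in res.dropped_constant


def test_cox_zero_events_rejected():
    df = _toy3()
    df["event"] = 0.0
    with pytest.raises(ValueError, match="event"):
        fit_cox(df, "time", "event", ["x"])


def test_cox_recovers_generative_log_hazard():
    """High-vs-low genetic category log-HR near its simulated set-point."""
    cfg = SimulationConfig(n_participants=50_000, seed=31)
    df = attach_genetic_risk(generate_cohort(cfg))
    df = df[df["prevalent_obesity"] == 0]
    res = fit_cox(df, "incident_obesity_time", "incident_obesity_event",
                  ["genetic_category"])
    est = res.params["genetic_category[high]"]
    se = res.se["genetic_category[high]"]
    # true contrast: per-SD log-hazard x (top-bottom quintile mean gap)
    truth = cfg.incident_obesity_hazard.per_sd_pgs * 2 * stats.norm.pdf(
        stats.norm.ppf(0.8)) / 0.2
    assert abs(est - truth) < 3 * se


# -- logistic oracle --------------------------------------------------------

def test_logistic_matches_2x2_closed_form():
    a, b, c, d = 10, 90, 30, 70  # exposed cases/non, unexposed cases/non
    y = [1] * a + [0] * b + [1] * c + [0] * d
    x = [1.0] * (a + b) + [0.0] * (c + d)
    df = pd.DataFrame({"y": np.array(y, float), "x": x})
    res = fit_logistic(df, "y", ["x"])
    expected = np.log(a * d / (b * c))
    assert res.params["x"] == pytest.approx(expected, abs=1e-6)


def test_logistic_null_predictor_ci_covers_one():
    rng = np.random.default_rng(6)
    df = pd.DataFrame({"y": rng.binomial(1, 0.3, 4000).astype(float),
                       "x": rng.normal(size=4000)})
    res = fit_logistic(df, "y", ["x"])
    lo, hi = np.exp(res.conf_int().loc["x"])
    assert lo < 1.0 < hi


def test_logistic_intercept_only_recovers_prevalence():
    df = pd.DataFrame({"y": [1.0] * 30 + [0.0] * 70})
    res = fit_logistic(df, "y", [])
    p = 1 / (1 + np.exp(-res.params["intercept"]))
    assert p == pytest.approx(0.3, abs=1e-8)


def test_logistic_perfect_separation_rejected():
    df = pd.DataFrame({"y": [0.0] * 50 + [1.0] * 50,
                       "x": list(np.linspace(0, 1, 50)) +
                            list(np.linspace(2, 3, 50))})
    with pytest.raises(ValueError):
        fit_logistic(df, "y", ["x"])


def test_wald_ci_construction():
    df = pd.DataFrame({"y": np.r_[np.ones(40), np.zeros(60),
                                  np.ones(20), np.zeros(80)],
                       "x": np.r_[np.ones(100), np.zeros(100)]})
    res = fit_logistic(df, "y", ["x"])
    summ = res.summary()
    manual_lo = np.exp(res.params["x"] - 1.959963984540054 * res.se["x"])
    assert summ.loc["x", "ci_low"] == pytest.approx(manual_lo, rel=1e-9)


# -- Breslow baseline and absolute risk ------------------------------------

def _exponential_cox_fixture(n=30_000, seed=12, lam=0.02, b_poor=0.7,
                             b_pgs=0.3, horizon=11.55):
    rng = np.random.default_rng(seed)
    poor = rng.binomial(1, 0.3, n).astype(float)
    pgs = rng.normal(size=n)
    age = rng.uniform(40, 70, n)
    rate = lam * np.exp(b_poor * poor + b_pgs * pgs)
    t = rng.exponential(1.0, n) / rate
    df = pd.DataFrame({
        "time": np.minimum(t, horizon), "event": (t <= horizon).astype(float),
        "lifestyle_category": np.where(poor == 1, "poor", "healthy"),
        "pgs_z": pgs, "age_enroll": age,
    })
    df["lifestyle_category"] = pd.Categorical(
        df["lifestyle_category"], categories=["poor", "intermediate", "healthy"])
    return df, dict(lam=lam, b_poor=b_poor, b_pgs=b_pgs)


def test_breslow_baseline_is_nondecreasing_step_function():
    df, _ = _exponential_cox_fixture(n=2000)
    res = fit_cox(df, "time", "event", ["lifestyle_category", "pgs_z"])
    base = res.baseline_cumulative_hazard()
    assert (base["cumhaz"] >= 0).all()
    assert base["cumhaz"].is_monotonic_increasing
    event_times = set(df.loc[df["event"] == 1, "time"])
    assert set(base["time"]) <= event_times


def test_breslow_baseline_matches_exponential_closed_form():
    df, truth = _exponential_cox_fixture()
    res = fit_cox(df, "time", "event", ["lifestyle_category", "pgs_z"])
    # cumulative hazard at x=0 should be ~ lam * t
    for t in (2.0, 5.0, 10.0):
        h0 = -np.log(res.baseline_survival_at(t))
        assert h0 == pytest.approx(truth["lam"] * t, rel=0.1)


def test_absolute_risk_matches_closed_form_survival():
    df, truth = _exponential_cox_fixture()
    res = fit_cox(df, "time", "event",
                  ["lifestyle_category", "pgs_z", "age_enroll"])
    t_star = 75.0 - df["age_enroll"].mean()
    for pct, group in [(50.0, "poor"), (50.0, "healthy"), (95.0, "poor")]:
        z = stats.norm.ppf(pct / 100)
        eta_true = truth["b_poor"] * (group == "poor") + truth["b_pgs"] * z
        expected = (1 - np.exp(-truth["lam"] * t_star * np.exp(eta_true))) * 100
        got = absolute_risk_by_age(res, group=group, pgs_percentile=pct)
        assert got == pytest.approx(expected, rel=0.12), (group, pct)


def test_absolute_risk_guards():
    df, _ = _exponential_cox_fixture(n=2000)
    res = fit_cox(df, "time", "event",
                  ["lifestyle_category", "pgs_z", "age_enroll"])
    with pytest.raises(ValueError):
        absolute_risk_by_age(res, group="poor", pgs_percentile=0.0)
    with pytest.raises(ValueError):
        absolute_risk_by_age(res, group="poor", pgs_percentile=50.0,
                             target_age=30.0)  # precedes enrollment ages
    with pytest.raises(ValueError):
        absolute_risk_by_age(res, group="luxurious", pgs_percentile=50.0)


def test_risk_monotone_in_percentile_and_zero_coefficient_flat():
    df, _ = _exponential_cox_fixture(n=10_000)
    res = fit_cox(df, "time", "event",
                  ["lifestyle_category", "pgs_z", "age_enroll"])
    curve = risk_gradient_curve(res, percentiles=[5, 25, 50, 75, 95])
    assert curve["poor_pct"].is_monotonic_increasing
    assert (curve["difference"] > 0).all()
    # widening on the absolute scale under log-linear effects
    assert curve["difference"].iloc[-1] > curve["difference"].iloc[0]

    # pin the lifestyle contrasts at zero: difference vanishes identically
    for col in res.params.index:
        if col.startswith("lifestyle_category["):
            res.params[col] = 0.0
    flat = risk_gradient_curve(res, percentiles=[5, 50, 95])
    np.testing.assert_allclose(flat["difference"], 0.0, atol=1e-12)


def test_risk_curve_poor_healthy_ratio_matches_generative_set_point():
    """A ~2x poor/healthy median-risk contrast is recovered from simulation."""
    df, truth = _exponential_cox_fixture(b_poor=np.log(2.0), b_pgs=0.22,
                                         lam=0.002)
    res = fit_cox(df, "time", "event",
                  ["lifestyle_category", "pgs_z", "age_enroll"])
    curve = risk_gradient_curve(res)
    ratio = curve["poor_pct"].median() / curve["healthy_pct"].median()
    assert ratio == pytest.approx(2.0, rel=0.15)


# -- joint grid and isolated effects ----------------------------------------

def test_joint_grid_structure(big_cohort):
    inc = big_cohort[big_cohort["prevalent_obesity"] == 0]
    grid = joint_category_grid(inc, endpoint="incident_obesity", family="cox")
    assert len(grid) == 9
    ref = grid[grid["reference"]]
    assert len(ref) == 1
    assert ref["HR"].iloc[0] == 1.0
    assert np.isnan(ref["ci_low"].iloc[0])
    assert grid["n"].sum() == len(inc.dropna(subset=["lifestyle_category"]))


def test_joint_grid_multiplicative_under_no_interaction(big_cohort):
    """Incident hazards are generated without a product term, so the
    high/poor cell should approximate the product of the marginal cells."""
    inc = big_cohort[big_cohort["prevalent_obesity"] == 0]
    grid = joint_category_grid(inc, endpoint="incident_obesity",
                               family="cox").set_index(
        ["genetic_category", "lifestyle_category"])
    joint = np.log(grid.loc[("high", "poor"), "HR"])
    marg = (np.log(grid.loc[("high", "healthy"), "HR"])
            + np.log(grid.loc[("low", "poor"), "HR"]))
    # SE of the log joint contrast from its CI width
    se_joint = (np.log(grid.loc[("high", "poor"), "ci_high"])
                - np.log(grid.loc[("high", "poor"), "ci_low"])) / (2 * 1.96)
    se_hh = (np.log(grid.loc[("high", "healthy"), "ci_high"])
             - np.log(grid.loc[("high", "healthy"), "ci_low"])) / (2 * 1.96)
    se_lp = (np.log(grid.loc[("low", "poor"), "ci_high"])
             - np.log(grid.loc[("low", "poor"), "ci_low"])) / (2 * 1.96)
    tol = 3 * np.sqrt(se_joint ** 2 + se_hh ** 2 + se_lp ** 2)
    assert abs(joint - marg) < tol


def test_joint_grid_supramultiplicative_with_positive_interaction():
    cfg = SimulationConfig(n_participants=40_000, seed=41,
                           beta_interaction=0.3)
    df = attach_genetic_risk(generate_cohort(cfg))
    grid = joint_category_grid(df, endpoint="prevalent_obesity",
                               family="logistic").set_index(
        ["genetic_category", "lifestyle_category"])
    joint = np.log(grid.loc[("high", "poor"), "OR"])
    marg = (np.log(grid.loc[("high", "healthy"), "OR"])
            + np.log(grid.loc[("low", "poor"), "OR"]))
    assert joint > marg


def test_isolated_effect_unconfounded_matches_unadjusted(big_cohort):
    """G and L are generated independently: adjustment changes little."""
    inc = big_cohort[big_cohort["prevalent_obesity"] == 0]
    adj = isolated_effect(inc, domain="genetic", endpoint="incident_obesity",
                          family="cox", covariates=[])
    unadj = fit_cox(inc, "incident_obesity_time", "incident_obesity_event",
                    ["genetic_category"])
    term = "genetic_category[high]"
    assert abs(adj.params[term] - unadj.params[term]) < 2 * adj.se[term]
    assert 0.0 < adj.trend_p < 1.0


def test_isolated_effect_recovers_truth_under_confounding():
    """Induced G-L correlation biases the crude fit; adjustment removes it."""
    cfg = SimulationConfig(n_participants=60_000, seed=47,
                           beta_interaction=0.0)
    df = attach_genetic_risk(generate_cohort(cfg))
    rng = np.random.default_rng(48)
    # selection that couples PGS with unfavorable lifestyle
    score = 1.2 * df["pgs_z"] * (df["unfavorable_count"] - 2.8)
    keep = rng.random(len(df)) < 1 / (1 + np.exp(-score))
    sel = df[keep]
    assert abs(np.corrcoef(sel["pgs_z"], sel["unfavorable_count"])[0, 1]) > 0.1

    crude = fit_logistic(sel, "prevalent_obesity", ["pgs_z"])
    adjusted = fit_logistic(sel, "prevalent_obesity",
                            ["pgs_z", "unfavorable_count"])
    truth = cfg.beta_pgs
    assert abs(adjusted.params["pgs_z"] - truth) < 3 * adjusted.se["pgs_z"]
    assert abs(crude.params["pgs_z"] - truth) > abs(
        adjusted.params["pgs_z"] - truth)


def test_isolated_effect_invalid_domain():
    with pytest.raises(ValueError, match="domain"):
        isolated_effect(pd.DataFrame(), domain="astrological")


def test_fit_risk_model_median_risks_near_study_pattern(big_cohort):
    """Median risk-by-75 sits near the few-percent range with poor > healthy."""
    inc = big_cohort[big_cohort["prevalent_obesity"] == 0]
    res = fit_risk_model(inc)
    curve = risk_gradient_curve(res)
    med_h = curve["healthy_pct"].median()
    med_p = curve["poor_pct"].median()
    assert 0.5 < med_h < med_p < 6.0
    assert curve["difference"].iloc[-1] > curve["difference"].iloc[0] > 0
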