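"""RERI, attributable proportions, product-term test, bootstrap."""

import numpy as np
import pandas as pd
import pytest

from gxlife import SimulationConfig, generate_cohort
from gxlife.interaction import (Contrast, InteractionModel, bootstrap_ci,
                                decompose, default_contrast,
                                multiplicative_test, reri_binary,
                                reri_continuous, reri_delta_ci)
from gxlife.models import FitResult


@pytest.mark.parametrize("rr11,rr10,rr01,expected", [
    (4.0, 2.0, 2.0, 1.0),
    (1.0, 1.0, 1.0, 0.0),
    (3.0, 2.0, 2.0, 0.0),  # exact additivity: RR11 = RR10 + RR01 - 1
])
def test_reri_binary_arithmetic(rr11, rr10, rr01, expected):
    assert reri_binary(rr11, rr10, rr01) == pytest.approx(expected, abs=1e-12)


def test_reri_binary_rejects_nonpositive():
    with pytest.raises(ValueError):
        reri_binary(2.0, 0.0, 1.0)
    with pytest.raises(ValueError):
        reri_binary(-1.0, 1.0, 1.0)


def test_decompose_known_arithmetic():
    d = decompose(5.0, 3.0, 2.0)
    assert d.ap_g == pytest.approx(0.5, abs=1e-12)
    assert d.ap_l == pytest.approx(0.25, abs=1e-12)
    assert d.ap_i == pytest.approx(0.25, abs=1e-12)
    assert d.reri == pytest.approx(1.0, abs=1e-12)


@pytest.mark.parametrize("rr11,rr10,rr01", [
    (5.0, 3.0, 2.0), (1.5, 1.2, 1.1), (22.0, 5.5, 2.7), (2.0, 1.9, 1.8),
])
def test_decompose_components_sum_to_one(rr11, rr10, rr01):
    d = decompose(rr11, rr10, rr01)
    assert d.ap_g + d.ap_l + d.ap_i == pytest.approx(1.0, abs=1e-12)


def test_decompose_undefined_when_no_excess_risk():
    with pytest.raises(ValueError, match="undefined"):
        decompose(0.9, 0.5, 0.6)


def _fit_with(bg, bl, bgl):
    params = pd.Series({"pgs_z": bg, "unfavorable_count": bl,
                        "pgs_z:unfavorable_count": bgl})
    cov = pd.DataFrame(np.eye(3) * 1e-4, index=params.index,
                       columns=params.index)
    return FitResult(params=params, cov=cov, loglik=0.0, n=0, n_events=0,
                     family="logistic", formula="synthetic coefficients")


def test_reri_continuous_direct_formula_evaluation():
    """Unit contrasts: RERI = e^(b1+b2+b3) - e^b1 - e^b2 + 1 exactly."""
    fit = _fit_with(0.5, 0.3, 0.2)
    c = Contrast(g0=0.0, g1=1.0, l0=0.0, l1=1.0)
    d = reri_continuous(fit, c)
    expected = np.exp(1.0) - np.exp(0.5) - np.exp(0.3) + 1.0
    assert d.reri == pytest.approx(expected, abs=1e-12)
    assert d.rr11 == pytest.approx(np.exp(1.0), abs=1e-12)


def test_reri_continuous_zero_product_term_curvature_sign():
    """Without a product term, RERI sign follows log-linear curvature."""
    fit = _fit_with(0.5, 0.3, 0.0)
    c = Contrast(g0=0.0, g1=1.0, l0=0.0, l1=1.0)
    d = reri_continuous(fit, c)
    # closed form: e^0.8 - e^0.5 - e^0.3 + 1 > 0 (convexity of exp)
    expected = np.exp(0.8) - np.exp(0.5) - np.exp(0.3) + 1.0
    assert d.reri == pytest.approx(expected, abs=1e-12)
    assert d.reri > 0


def test_reri_continuous_exposure_label_swap_symmetry():
    fit = _fit_with(0.4, 0.7, 0.1)
    c = Contrast(g0=-1.0, g1=1.0, l0=0.5, l1=4.5)
    d1 = reri_continuous(fit, c)

    swapped = pd.Series({"pgs_z": 0.7, "unfavorable_count": 0.4,
                         "pgs_z:unfavorable_count": 0.1})
    fit2 = FitResult(params=swapped, cov=pd.DataFrame(
        np.eye(3) * 1e-4, index=swapped.index, columns=swapped.index),
        loglik=0.0, n=0, n_events=0, family="logistic", formula="swap")
    c2 = Contrast(g0=0.5, g1=4.5, l0=-1.0, l1=1.0)
    d2 = reri_continuous(fit2, c2)
    assert d1.reri == pytest.approx(d2.reri, rel=1e-12)


def test_reri_continuous_requires_product_term():
    params = pd.Series({"pgs_z": 0.5, "unfavorable_count": 0.3})
    fit = FitResult(params=params,
                    cov=pd.DataFrame(np.eye(2), index=params.index,
                                     columns=params.index),
                    loglik=0.0, n=0, n_events=0, family="logistic",
                    formula="no product")
    with pytest.raises(KeyError):
        reri_continuous(fit)


def test_multiplicative_test_constant_product_flagged():
    df = pd.DataFrame({
        "pgs_z": np.zeros(100),
        "unfavorable_count": np.tile([1.0, 2.0], 50),
        "prevalent_obesity": np.tile([0.0, 1.0], 50),
    })
    with pytest.raises(ValueError, match="constant"):
        multiplicative_test(df, covariates=[])


def test_multiplicative_test_detects_strong_interaction():
    """beta_interaction = 0.1 at n = 50,000 is decisively detected."""
    from gxlife.genetics import attach_genetic_risk

    cfg = SimulationConfig(n_participants=50_000, seed=19,
                           beta_interaction=0.1)
    df = attach_genetic_risk(generate_cohort(cfg))
    res = multiplicative_test(df, covariates=[])
    assert res.p_interaction < 0.001
    assert res.params["pgs_z:unfavorable_count"] > 0


def test_binary_and_continuous_reri_agree_on_binary_exposures():
    """A 0/1-coded continuous fit with unit contrasts reproduces the
    contingency-table RERI within sampling noise."""
    rng = np.random.default_rng(23)
    n = 50_000
    g = rng.binomial(1, 0.3, n).astype(float)
    l = rng.binomial(1, 0.4, n).astype(float)
    eta = -2.5 + 0.9 * g + 0.6 * l + 0.25 * g * l
    y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(float)
    df = pd.DataFrame({"pgs_z": g, "unfavorable_count": l,
                       "prevalent_obesity": y})

    fit = multiplicative_test(df, covariates=[])
    d_cont = reri_continuous(fit, Contrast(g0=0.0, g1=1.0, l0=0.0, l1=1.0))

    # contingency-table ORs against the double-unexposed cell
    def odds(gv, lv):
        sub = df[(df["pgs_z"] == gv) & (df["unfavorable_count"] == lv)]
        p = sub["prevalent_obesity"].mean()
        return p / (1 - p)

    o00 = odds(0, 0)
    rr11, rr10, rr01 = odds(1, 1) / o00, odds(1, 0) / o00, odds(0, 1) / o00
    d_tab = reri_binary(rr11, rr10, rr01)
    # saturated model: the two routes agree up to float noise
    assert d_cont.reri == pytest.approx(d_tab, rel=1e-6)


def test_reri_sampling_distribution_centred_at_zero_under_null():
    """With no product term and no main effects, RERI centres on 0."""
    rng = np.random.default_rng(29)
    n, reps = 4000, 60
    estimates = []
    for _ in range(reps):
        g = rng.normal(size=n)
        l = rng.uniform(0, 5, n)
        y = rng.binomial(1, 0.2, n).astype(float)
        df = pd.DataFrame({"pgs_z": g, "unfavorable_count": l,
                           "prevalent_obesity": y})
        fit = multiplicative_test(df, covariates=[])
        estimates.append(reri_continuous(fit, default_contrast()).reri)
    mc_se = np.std(estimates, ddof=1) / np.sqrt(reps)
    assert abs(np.mean(estimates)) < 3 * mc_se


def test_genetic_dominant_calibration_recovers_ap_ordering():
    """A configuration whose true joint-effect split gives the genetic
    share ~57% recovers AP_G > AP_L > AP_I in the replicate-mean
    decomposition (single-cohort AP estimates are noisy by design)."""
    from gxlife.config import calibrated_interaction_config

    aps = []
    for seed in range(100):
        cfg = calibrated_interaction_config(n_participants=50_000, seed=seed)
        df = generate_cohort(cfg)
        fit = multiplicative_test(df, pgs_col="pgs_raw", covariates=[])
        d = reri_continuous(fit, pgs_term="pgs_raw")
        aps.append((d.ap_g, d.ap_l, d.ap_i))
    ap_g, ap_l, ap_i = np.mean(aps, axis=0)
    assert ap_g > ap_l > ap_i
    assert 0.50 < ap_g < 0.65  # genetic share dominates


# -- bootstrap --------------------------------------------------------------

def test_bootstrap_deterministic_given_seed():
    rng = np.random.default_rng(5)
    df = pd.DataFrame({"x": rng.normal(size=300)})
    est = lambda d: {"mean": d["x"].mean()}
    a = bootstrap_ci(df, est, b=100, seed=9)
    b = bootstrap_ci(df, est, b=100, seed=9)
    assert a == b
    c = bootstrap_ci(df, est, b=100, seed=10)
    assert a["mean"] != c["mean"]


def test_bootstrap_degenerate_data_zero_width():
    df = pd.DataFrame({"x": np.full(50, 3.14)})
    ci = bootstrap_ci(df, lambda d: {"mean": d["x"].mean()}, b=100, seed=1)
    lo, hi = ci["mean"]
    assert lo == hi == pytest.approx(3.14)


def test_bootstrap_rejects_small_b_and_failing_estimator():
    df = pd.DataFrame({"x": np.arange(10.0)})
    with pytest.raises(ValueError, match="B >= 100"):
        bootstrap_ci(df, lambda d: {"m": 0.0}, b=10, seed=0)

    def flaky(d):
        raise RuntimeError("always fails")

    with pytest.raises(RuntimeError, match="resamples failed"):
        bootstrap_ci(df, flaky, b=100, seed=0)


def test_delta_method_ci_brackets_point_estimate():
    fit = _fit_with(0.5, 0.3, 0.2)
    c = Contrast(g0=0.0, g1=1.0, l0=0.0, l1=1.0)
    lo, hi = reri_delta_ci(fit, c)
    point = reri_continuous(fit, c).reri
    assert lo < point < hi


def test_interaction_model_end_to_end_with_bootstrap():
    from gxlife.genetics import attach_genetic_risk

    cfg = SimulationConfig(n_participants=8000, seed=3)
    df = attach_genetic_risk(generate_cohort(cfg))
    res = InteractionModel(df, covariates=[]).fit(bootstrap_b=100, seed=1)
    summ = res.summary()
    assert summ.loc["AP_genetic", "value"] + summ.loc["AP_lifestyle", "value"] \
        + summ.loc["AP_interaction", "value"] == pytest.approx(1.0, abs=1e-12)
    assert summ.loc["RERI", "ci_low"] <= summ.loc["RERI", "value"] \
        <= summ.loc["RERI", "ci_high"]
    assert res.decomposition.bootstrap_b == 100
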