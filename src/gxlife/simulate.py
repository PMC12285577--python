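"""Synthetic cohort generator.

Emulates the statistical structure of a middle-aged population cohort with
genetic and lifestyle data so every downstream analysis stage is testable
without access-controlled data:

* raw lifestyle measures drawn from simple parametric families whose
  parameters are inverse-calibrated so the downstream classification rules
  reproduce the configured favorable-fraction prevalences in expectation;
* a standard-normal polygenic score (PGS);
* baseline BMI from a linear model in PGS and unfavorable-factor count plus
  Gaussian noise, with body fat %, waist circumference and waist-to-hip
  ratio as correlated adiposity indices;
* prevalent obesity from a logistic liability with PGS, lifestyle and a
  PGS x lifestyle product term;
* incident obesity and 20 obesity-related morbidity (ORM) endpoints from
  exponential-baseline proportional-hazards models with administrative
  censoring at a fixed follow-up horizon — by default the genetic effect on
  the ORMs is wholly mediated by BMI (no direct PGS term);
* optional missingness injection in BMI and outcome fields.

All randomness flows from a single seed; per-stage substreams are spawned
deterministically, so output is bit-identical for identical (config, seed).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .config import FACTOR_NAMES, SimulationConfig
from .lifestyle import attach_lifestyle

_STREAMS = (
    "covariates", "pgs", "lifestyle", "bmi", "prevalent",
    "incident", "orm", "missing",
)


def _substreams(seed: int) -> dict[str, np.random.Generator]:
    children = np.random.SeedSequence(seed).spawn(len(_STREAMS))
    return {name: np.random.default_rng(seq)
            for name, seq in zip(_STREAMS, children)}


# ---------------------------------------------------------------------------
# raw-measure calibration: parametric families inverted at the target
# favorable fraction, so classify_factors reproduces it in expectation
# ---------------------------------------------------------------------------

def _diet_binom_p(target: float) -> float:
    # P(Binom(8, q) >= 4) = target
    return optimize.brentq(lambda q: stats.binom.sf(3, 8, q) - target, 1e-9, 1 - 1e-9)

def _met_scale(target: float) -> float:
    # X ~ Exp(scale); P(X > 3000) = target
    return -3000.0 / np.log(target)

def _screen_scale(target: float) -> float:
    # X ~ Gamma(shape=2, scale); P(X <= 2) = target
    return optimize.brentq(
        lambda th: stats.gamma.cdf(2.0, a=2.0, scale=th) - target, 1e-6, 1e3)

def _alcohol_scale(target: float, cutoff: float) -> float:
    # X ~ Exp(scale); P(X <= cutoff) = target
    return -cutoff / np.log1p(-target)

def _sleep_sd(target: float) -> float:
    # X ~ N(7, sd); P(6 <= X <= 8) = target
    return 1.0 / stats.norm.ppf((1.0 + target) / 2.0)


def generate_cohort(config: SimulationConfig) -> pd.DataFrame:
    """Generate a cohort table per the configured generative model.

    Returns a DataFrame with one row per participant carrying raw lifestyle
    measures, derived lifestyle indicators/score/category, PGS, covariates,
    BMI and adiposity indices, the prevalent-obesity liability flag, and
    (event, time) pairs for incident obesity and every ORM endpoint.
    Provenance (seed, config hash) lives in ``df.attrs["provenance"]``.
    """
    config.validate()
    n = config.n_participants
    rng = _substreams(config.seed)
    cov = config.covariate_dists

    df = pd.DataFrame(index=pd.RangeIndex(n))
    df["participant_id"] = [f"S{i:07d}" for i in range(n)]

    # covariates -----------------------------------------------------------
    r = rng["covariates"]
    df["age_enroll"] = r.uniform(cov.age_min, cov.age_max, n)
    df["sex"] = np.where(r.random(n) < cov.female_fraction, "female", "male")
    df["sex_male"] = (df["sex"] == "male").astype(float)
    for k in range(1, cov.n_pcs + 1):
        df[f"pc{k}"] = r.normal(0.0, cov.pc_scale, n)
    df["education_high"] = (r.random(n) < 0.43).astype(float)
    df["deprivation_tertile"] = r.choice(
        ["low", "mid", "high"], size=n, p=[0.2, 0.6, 0.2])
    df["smoking_status"] = r.choice(
        ["never", "previous", "current"], size=n, p=[0.55, 0.35, 0.10])
    df["diabetes"] = (r.random(n) < 0.025).astype(float)
    df["depression"] = (r.random(n) < 0.006).astype(float)
    df["hypothyroidism"] = (r.random(n) < 0.009).astype(float)
    df["cushing"] = (r.random(n) < 1e-4).astype(float)
    df["pcos"] = np.where(df["sex"] == "female",
                          (r.random(n) < 4e-4).astype(float), 0.0)
    df["weight_gain_med"] = (r.random(n) < 0.061).astype(float)
    df["genotyping_array"] = (r.random(n) < 0.8).astype(float)

    # polygenic score ------------------------------------------------------
    df["pgs_raw"] = rng["pgs"].normal(0.0, 1.0, n)

    # raw lifestyle measures ----------------------------------------------
    r = rng["lifestyle"]
    targets = dict(zip(FACTOR_NAMES, config.factor_prevalences))
    df["met_min_week"] = r.exponential(_met_scale(targets["physical_activity"]), n)
    df["diet_criteria_met"] = r.binomial(8, _diet_binom_p(targets["diet"]), n)
    df["screen_hours_day"] = r.gamma(2.0, _screen_scale(targets["sedentary"]), n)
    alc = np.empty(n)
    for sex, cutoff in (("female", 14.0), ("male", 28.0)):
        mask = (df["sex"] == sex).to_numpy()
        alc[mask] = r.exponential(
            _alcohol_scale(targets["alcohol"], cutoff), mask.sum())
    df["alcohol_g_day"] = alc
    df["sleep_hours_day"] = np.clip(
        r.normal(7.0, _sleep_sd(targets["sleep"]), n), 0.0, None)

    df = attach_lifestyle(df)
    unfav = df["unfavorable_count"].to_numpy(dtype=float)
    pgs = df["pgs_raw"].to_numpy()

    # BMI and correlated adiposity indices --------------------------------
    r = rng["bmi"]
    bm = config.bmi_model
    df["bmi"] = (bm.intercept + bm.per_sd_pgs * pgs + bm.per_factor * unfav
                 + r.normal(0.0, bm.noise_sd, n))
    bmi = df["bmi"].to_numpy()
    female = (df["sex"] == "female").to_numpy()
    df["body_fat_pct"] = np.clip(
        2.0 + 1.1 * bmi + 8.0 * female + r.normal(0.0, 3.0, n), 3.0, 70.0)
    df["waist_circumference_cm"] = np.clip(
        30.0 + 2.2 * bmi - 6.0 * female + r.normal(0.0, 5.0, n), 40.0, None)
    df["waist_hip_ratio"] = np.clip(
        0.70 + 0.004 * bmi + 0.10 * (~female) + r.normal(0.0, 0.04, n), 0.5, 1.4)

    # prevalent obesity: logistic liability with G x L product term -------
    eta = (config.beta0 + config.beta_pgs * pgs + config.beta_lifestyle * unfav
           + config.beta_interaction * pgs * unfav)
    p = 1.0 / (1.0 + np.exp(-eta))
    df["prevalent_obesity"] = (rng["prevalent"].random(n) < p).astype(float)

    # incident obesity ----------------------------------------------------
    _draw_endpoint(df, config.incident_obesity_hazard, config.censor_years,
                   rng["incident"], prefix="incident_obesity")

    df.attrs["provenance"] = {
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "n_participants": n,
    }
    return df


def _draw_endpoint(df: pd.DataFrame, spec, horizon: float,
                   r: np.random.Generator, prefix: str) -> None:
    n = len(df)
    bmi = df["bmi"].to_numpy(dtype=float)
    pgs = df["pgs_raw"].to_numpy(dtype=float)
    unfav = df["unfavorable_count"].to_numpy(dtype=float)
    log_rate = (np.log(spec.baseline_rate)
                + spec.per_bmi * (bmi - 25.0)
                + spec.per_sd_pgs * pgs
                + spec.per_factor * unfav)
    # exponential baseline: T ~ Exp(rate), administrative censoring at horizon
    with np.errstate(over="ignore"):
        t = r.exponential(1.0, n) / np.exp(log_rate)
    event = t <= horizon
    time = np.minimum(t, horizon)
    missing = ~np.isfinite(log_rate)  # e.g. missing BMI
    df[f"{prefix}_event"] = np.where(missing, np.nan, event.astype(float))
    df[f"{prefix}_time"] = np.where(missing, np.nan, time)


def simulate_orm_endpoints(cohort: pd.DataFrame,
                           config: SimulationConfig) -> pd.DataFrame:
    """Append the 20 ORM time-to-event endpoints to a generated cohort.

    Each endpoint's hazard depends on BMI (the mediated path) and
    optionally on a direct PGS term; the default configuration sets the
    direct effect to 0 so the PGS acts on the ORMs only through BMI.
    Records with missing BMI get missing endpoint fields.
    """
    df = cohort.copy()
    r = _substreams(config.seed)["orm"]
    for spec in config.orm_hazards:
        _draw_endpoint(df, spec, config.censor_years, r, prefix=spec.name)
    df.attrs["provenance"] = dict(cohort.attrs.get("provenance", {}))
    df.attrs["provenance"]["orm_endpoints"] = [s.name for s in config.orm_hazards]
    return df


def inject_missingness(cohort: pd.DataFrame,
                       config: SimulationConfig) -> pd.DataFrame:
    """Blank BMI and outcome fields independently at the configured rates.

    Mirrors an exclusion flow where a participant can be missing BMI,
    outcome data, or both by chance; the counts of each missingness pattern
    are recorded in the provenance metadata.
    """
    df = cohort.copy()
    r = _substreams(config.seed)["missing"]
    n = len(df)
    miss_bmi = r.random(n) < config.missing_bmi_rate
    miss_out = r.random(n) < config.missing_outcome_rate

    df.loc[miss_bmi, "bmi"] = np.nan
    outcome_cols = [c for c in df.columns
                    if c.endswith("_event") or c.endswith("_time")]
    df.loc[miss_out, outcome_cols] = np.nan
    df["missing_bmi"] = miss_bmi
    df["missing_outcome"] = miss_out

    df.attrs["provenance"] = dict(cohort.attrs.get("provenance", {}))
    df.attrs["provenance"]["missingness"] = {
        "missing_bmi": int(miss_bmi.sum()),
        "missing_outcome": int(miss_out.sum()),
        "missing_both": int((miss_bmi & miss_out).sum()),
        "rates": [config.missing_bmi_rate, config.missing_outcome_rate],
    }
    return df


def simulate(config: SimulationConfig) -> pd.DataFrame:
    """Full generation pipeline: cohort, ORM endpoints, missingness."""
    df = generate_cohort(config)
    df = simulate_orm_endpoints(df, config)
    return inject_missingness(df, config)


# ---------------------------------------------------------------------------
# I/O: tab-delimited cohort with a JSON provenance sidecar
# ---------------------------------------------------------------------------

def write_cohort(df: pd.DataFrame, path) -> None:
    path = Path(path)
    df.to_csv(path, sep="\t", index=False)
    sidecar = path.with_suffix(path.suffix + ".provenance.json")
    with open(sidecar, "w") as fh:
        json.dump(df.attrs.get("provenance", {}), fh, indent=2)


def read_cohort(path) -> pd.DataFrame:
    path = Path(path)
    df = pd.read_csv(path, sep="\t",
                     dtype={"participant_id": str},
                     keep_default_na=True)
    for col in ("lifestyle_category",):
        if col in df.columns:
            from .lifestyle import CATEGORY_ORDER
            df[col] = pd.Categorical(df[col], categories=CATEGORY_ORDER)
    if "genetic_category" in df.columns:
        from .genetics import GENETIC_CATEGORY_ORDER
        df["genetic_category"] = pd.Categorical(
            df["genetic_category"], categories=GENETIC_CATEGORY_ORDER)
    sidecar = path.with_suffix(path.suffix + ".provenance.json")
    if sidecar.exists():
        with open(sidecar) as fh:
            df.attrs["provenance"] = json.load(fh)
    return df
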