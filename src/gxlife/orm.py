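"""Obesity-related morbidity (ORM) association scan and BMI mediation.

Twenty time-to-event morbidity endpoints are each compared between
high-PGS carriers (top 20% of the standardized polygenic score) and the
remaining 80% (reference group) with adjusted proportional-hazards models.
Two follow-up analyses probe how lifestyle and BMI shape the genetic
association:

* lifestyle subgroups — high-PGS carriers are split into healthy vs
  unfavorable lifestyle (unfavorable = poor or intermediate) and each
  subgroup is contrasted against everyone outside it;
* BMI adjustment — refitting with baseline BMI in the design tests
  mediation: if the PGS acts on a morbidity only through BMI, the adjusted
  hazard ratio attenuates toward 1.

Multiplicity is handled with a nominal 0.05 replication flag and a
Bonferroni flag at 0.05 / m (strict inequality).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .genetics import top_fraction_flag
from .models import covariate_preset, fit_cox

NOMINAL_ALPHA = 0.05


def bonferroni(p_values, m: int | None = None) -> pd.Series:
    """Flag p-values significant at the Bonferroni threshold 0.05/m."""
    p = pd.Series(np.asarray(p_values, dtype=float))
    if hasattr(p_values, "index"):
        p.index = p_values.index
    valid = p.dropna()
    if ((valid < 0) | (valid > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    if m is None:
        m = len(p)
    if m < 1:
        raise ValueError("m must be >= 1")
    return (p < NOMINAL_ALPHA / m).where(p.notna()).rename("bonferroni")


def _endpoint_names(cohort: pd.DataFrame) -> list[str]:
    names = sorted({c[:-len("_event")] for c in cohort.columns
                    if c.startswith("orm_") and c.endswith("_event")})
    if not names:
        raise ValueError("no ORM endpoint columns (orm_*_event) in cohort")
    return names


def _scan(cohort: pd.DataFrame, endpoints: list[str], exposure_col: str,
          contrast_label: str, covariates: list[str],
          adjust_bmi: bool) -> list[dict]:
    rows = []
    covs = list(covariates) + (["bmi"] if adjust_bmi else [])
    for name in endpoints:
        row = {"endpoint": name, "contrast": contrast_label,
               "bmi_adjusted": adjust_bmi}
        events = cohort[f"{name}_event"]
        if events.fillna(0).sum() == 0 or cohort[exposure_col].dropna().nunique() < 2:
            row.update({"HR": np.nan, "ci_low": np.nan, "ci_high": np.nan,
                        "p": np.nan, "n": int(events.notna().sum()),
                        "n_events": int(events.fillna(0).sum()),
                        "estimable": False})
            rows.append(row)
            continue
        res = fit_cox(cohort, f"{name}_time", f"{name}_event",
                      [exposure_col] + covs)
        summ = res.summary()
        row.update({
            "HR": summ.loc[exposure_col, "HR"],
            "ci_low": summ.loc[exposure_col, "ci_low"],
            "ci_high": summ.loc[exposure_col, "ci_high"],
            "p": summ.loc[exposure_col, "p"],
            "log_hr": summ.loc[exposure_col, "estimate"],
            "n": res.n, "n_events": res.n_events, "estimable": True,
        })
        rows.append(row)
    return rows


def _finalize(rows: list[dict], m: int) -> pd.DataFrame:
    df = pd.DataFrame(rows)
    df["replicated"] = pd.array(df["p"] < NOMINAL_ALPHA, dtype="boolean")
    df["bonferroni"] = pd.array(df["p"] < NOMINAL_ALPHA / m, dtype="boolean")
    df.loc[df["p"].isna(), ["replicated", "bonferroni"]] = pd.NA
    return df


def orm_association_scan(cohort: pd.DataFrame,
                         endpoints: list[str] | None = None,
                         covariates: list[str] | None = None,
                         adjust_bmi: bool = False) -> pd.DataFrame:
    """High-PGS (top 20%) vs remaining-80% hazard for each morbidity.

    One adjusted Cox fit per endpoint; returns a tidy table with HR, CI,
    p, and the nominal/Bonferroni flags (m = number of endpoints).
    """
    endpoints = endpoints or _endpoint_names(cohort)
    df = cohort.copy()
    df["pgs_top20"] = top_fraction_flag(df["pgs_z"], 0.2).astype(float)
    if covariates is None:
        covariates = covariate_preset("main", df, with_pgs=True)
    rows = _scan(df, endpoints, "pgs_top20", "top20_vs_rest",
                 covariates, adjust_bmi)
    return _finalize(rows, m=len(endpoints))


def lifestyle_subgroups(cohort: pd.DataFrame,
                        endpoints: list[str] | None = None,
                        covariates: list[str] | None = None,
                        adjust_bmi: bool = False) -> pd.DataFrame:
    """Split high-PGS carriers by lifestyle and contrast each vs the rest.

    Two rows per endpoint: (top-20% PGS and healthy lifestyle) vs everyone
    else, and (top-20% PGS and unfavorable lifestyle) vs everyone else,
    where unfavorable pools the poor and intermediate categories.
    """
    endpoints = endpoints or _endpoint_names(cohort)
    df = cohort.copy()
    top = top_fraction_flag(df["pgs_z"], 0.2).astype(float)
    healthy = (df["lifestyle_category"].astype(str) == "healthy")
    unfavorable = df["lifestyle_category"].astype(str).isin(
        ["poor", "intermediate"])
    df["top20_healthy"] = (top.astype(bool) & healthy).astype(float)
    df["top20_unfavorable"] = (top.astype(bool) & unfavorable).astype(float)
    if covariates is None:
        covariates = covariate_preset("main", df, with_pgs=True)

    rows = _scan(df, endpoints, "top20_healthy", "top20_healthy_vs_rest",
                 covariates, adjust_bmi)
    rows += _scan(df, endpoints, "top20_unfavorable",
                  "top20_unfavorable_vs_rest", covariates, adjust_bmi)
    return _finalize(rows, m=len(endpoints))


def bmi_adjusted_scan(cohort: pd.DataFrame,
                      endpoints: list[str] | None = None,
                      covariates: list[str] | None = None) -> pd.DataFrame:
    """Mediation-by-adjustment: the PGS scan with and without baseline BMI.

    Returns one row per endpoint with unadjusted and BMI-adjusted HRs and
    the attenuation ratio (adjusted log-HR / unadjusted log-HR); full
    mediation drives the adjusted HR toward 1 and the ratio toward 0.
    """
    endpoints = endpoints or _endpoint_names(cohort)
    unadj = orm_association_scan(cohort, endpoints, covariates,
                                 adjust_bmi=False)
    adj = orm_association_scan(cohort, endpoints, covariates, adjust_bmi=True)
    merged = unadj.merge(
        adj[["endpoint", "HR", "ci_low", "ci_high", "p", "log_hr"]],
        on="endpoint", suffixes=("", "_bmi_adjusted"))
    with np.errstate(divide="ignore", invalid="ignore"):
        merged["attenuation_ratio"] = (
            merged["log_hr_bmi_adjusted"] / merged["log_hr"])
    return merged


def median_followup(cohort: pd.DataFrame,
                    endpoints: list[str] | None = None) -> float:
    """Median follow-up time across all ORM endpoint records."""
    endpoints = endpoints or _endpoint_names(cohort)
    times = pd.concat([cohort[f"{e}_time"] for e in endpoints])
    return float(times.median())
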