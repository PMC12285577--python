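"""Composite and weighted healthy-lifestyle scoring.

Five obesogenic lifestyle factors are classified from raw measures into
binary favorable/unfavorable indicators:

* physical activity — favorable iff MET minutes/week strictly exceed 3000;
* diet — favorable iff at least 4 of the 8 healthy-diet criteria are met;
* sedentary behavior — favorable iff screen time is at most 2 h/day;
* alcohol — favorable iff intake is <=14 g/day (women) or <=28 g/day (men);
* sleep — favorable iff duration lies in the closed interval [6, 8] h/day.

Participants score one point per favorable factor (0-5), banded into
``poor`` (0-1), ``intermediate`` (2-3) and ``healthy`` (4-5) lifestyle
categories. A weighted variant replaces the unit points with
obesity-association weights, rescaled so the weighted score also spans
[0, 5]: ``(b1*x1 + ... + b5*x5) * 5 / sum(b)``; the weighted score uses
the same numeric bands, with half-open edges [0,2), [2,4), [4,5].
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

INDICATOR_COLUMNS = [
    "fav_physical_activity",
    "fav_diet",
    "fav_sedentary",
    "fav_alcohol",
    "fav_sleep",
]

CATEGORY_ORDER = ["poor", "intermediate", "healthy"]

#: raw-measure column expected per indicator
RAW_MEASURES = {
    "fav_physical_activity": "met_min_week",
    "fav_diet": "diet_criteria_met",
    "fav_sedentary": "screen_hours_day",
    "fav_alcohol": "alcohol_g_day",
    "fav_sleep": "sleep_hours_day",
}

MET_CUTOFF = 3000.0
DIET_CRITERIA_REQUIRED = 4
SCREEN_CUTOFF_H = 2.0
ALCOHOL_CUTOFF_G = {"female": 14.0, "male": 28.0}
SLEEP_RANGE_H = (6.0, 8.0)

MIN_WEIGHT_FIT_N = 500


def classify_factors(cohort: pd.DataFrame) -> pd.DataFrame:
    """Classify the five lifestyle factors from raw measures.

    Parameters
    ----------
    cohort
        Must contain ``met_min_week``, ``diet_criteria_met``,
        ``screen_hours_day``, ``alcohol_g_day``, ``sleep_hours_day`` and
        ``sex`` (``"female"``/``"male"``). Missing raw measures yield
        missing indicators; negative measures are rejected.

    Returns
    -------
    DataFrame with the five ``fav_*`` indicator columns (float 0/1, NaN
    where the raw measure is missing), indexed like ``cohort``.
    """
    for col in RAW_MEASURES.values():
        if col not in cohort.columns:
            raise KeyError(f"cohort is missing raw measure column {col!r}")
        vals = cohort[col]
        if (vals.dropna() < 0).any():
            raise ValueError(f"negative values in {col!r} are not a valid measure")

    out = pd.DataFrame(index=cohort.index)
    out["fav_physical_activity"] = _binary(cohort["met_min_week"] > MET_CUTOFF,
                                           cohort["met_min_week"])
    out["fav_diet"] = _binary(cohort["diet_criteria_met"] >= DIET_CRITERIA_REQUIRED,
                              cohort["diet_criteria_met"])
    out["fav_sedentary"] = _binary(cohort["screen_hours_day"] <= SCREEN_CUTOFF_H,
                                   cohort["screen_hours_day"])

    sex = cohort["sex"]
    cutoff = sex.map(ALCOHOL_CUTOFF_G)  # NaN for unknown sex
    alcohol_fav = cohort["alcohol_g_day"] <= cutoff
    alcohol_missing = cohort["alcohol_g_day"].isna() | cutoff.isna()
    out["fav_alcohol"] = np.where(alcohol_missing, np.nan,
                                  alcohol_fav.astype(float))

    lo, hi = SLEEP_RANGE_H
    sleep = cohort["sleep_hours_day"]
    out["fav_sleep"] = _binary((sleep >= lo) & (sleep <= hi), sleep)
    return out


def _binary(condition: pd.Series, raw: pd.Series) -> np.ndarray:
    return np.where(raw.isna(), np.nan, condition.astype(float))


def composite_score(indicators: pd.DataFrame) -> pd.Series:
    """Sum of the five favorable indicators (0-5); NaN if any is missing."""
    missing = [c for c in INDICATOR_COLUMNS if c not in indicators.columns]
    if missing:
        raise KeyError(f"missing indicator columns: {missing}")
    block = indicators[INDICATOR_COLUMNS]
    score = block.sum(axis=1, min_count=5)  # NaN propagates: complete case only
    return score.rename("lifestyle_score")


def categorize(score) -> pd.Series:
    """Band a 0-5 lifestyle score (raw or weighted) into the three groups.

    poor iff score < 2; intermediate iff 2 <= score < 4; healthy iff
    score >= 4. Scores outside [0, 5] are rejected; NaN stays NaN.
    """
    s = pd.Series(np.asarray(score, dtype=float))
    valid = s.dropna()
    if ((valid < 0) | (valid > 5)).any():
        raise ValueError("lifestyle score outside [0, 5]")
    cat = pd.cut(s, bins=[-np.inf, 2, 4, np.inf], right=False,
                 labels=CATEGORY_ORDER)
    cat = cat.cat.set_categories(CATEGORY_ORDER)
    if hasattr(score, "index"):
        cat.index = score.index
    return cat.rename("lifestyle_category")


@dataclass
class LifestyleWeights:
    """Per-factor obesity-association weights for the weighted score.

    ``b`` holds the absolute values of the five favorable-indicator
    coefficients from a mutually adjusted logistic regression of prevalent
    obesity on all five indicators plus covariates.
    """

    b: dict[str, float]
    source_fit: object = None

    def __post_init__(self) -> None:
        if set(self.b) != set(INDICATOR_COLUMNS):
            raise ValueError(f"weights must cover exactly {INDICATOR_COLUMNS}")
        vals = np.array([self.b[c] for c in INDICATOR_COLUMNS], dtype=float)
        if not np.all(np.isfinite(vals)):
            raise ValueError("weights must be finite")
        if vals.sum() <= 0:
            raise ValueError("sum of weights must be > 0")

    def as_array(self) -> np.ndarray:
        return np.array([self.b[c] for c in INDICATOR_COLUMNS], dtype=float)

    def to_json(self, path) -> None:
        payload = {"b": self.b}
        if self.source_fit is not None and hasattr(self.source_fit, "fit_hash"):
            payload["source_fit_hash"] = self.source_fit.fit_hash()
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "LifestyleWeights":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(b=payload["b"])


def estimate_weights(cohort: pd.DataFrame, *,
                     outcome: str = "prevalent_obesity",
                     covariates: list[str] | None = None,
                     mutually_adjusted: bool = True,
                     min_n: int = MIN_WEIGHT_FIT_N) -> LifestyleWeights:
    """Estimate per-factor weights from the prevalent-obesity association.

    Fits a logistic regression of ``outcome`` on all five favorable
    indicators (mutually adjusted, the default) or one factor at a time,
    plus ``covariates``; the weights are the absolute values of the
    indicator coefficients (favorable indicators carry negative
    obesity-scale coefficients).
    """
    from .models import LogisticModel

    if covariates is None:
        covariates = [c for c in ("age_enroll", "sex_male") if c in cohort.columns]
    cols = INDICATOR_COLUMNS + covariates + [outcome]
    data = cohort[cols].dropna()
    if len(data) < min_n:
        raise ValueError(
            f"need at least {min_n} complete-case rows to estimate lifestyle "
            f"weights, got {len(data)}"
        )

    def _blame_and_raise(exc: Exception):
        # name the factor whose levels separate the outcome, if any
        for col in INDICATOR_COLUMNS:
            for level in (0.0, 1.0):
                side = data.loc[data[col] == level, outcome]
                if len(side) and side.nunique() < 2:
                    raise ValueError(
                        f"weight estimation failed: factor {col!r} separates "
                        f"the outcome (all level-{level:g} rows share one "
                        f"outcome)") from exc
        raise ValueError(f"weight estimation failed: {exc}") from exc

    b: dict[str, float] = {}
    try:
        if mutually_adjusted:
            res = LogisticModel(data, outcome=outcome,
                                covariates=INDICATOR_COLUMNS + covariates).fit()
            for col in INDICATOR_COLUMNS:
                b[col] = abs(float(res.params[col]))
            source = res
        else:
            source = None
            for col in INDICATOR_COLUMNS:
                res = LogisticModel(data, outcome=outcome,
                                    covariates=[col] + covariates).fit()
                b[col] = abs(float(res.params[col]))
    except ValueError as exc:
        _blame_and_raise(exc)
    return LifestyleWeights(b=b, source_fit=source)


def weighted_score(indicators: pd.DataFrame,
                   weights: LifestyleWeights) -> pd.Series:
    """Weighted lifestyle score ``(sum_i b_i x_i) * 5 / sum_i b_i`` in [0, 5].

    Reduces exactly to the raw 0-5 count when all weights are equal; equals
    5 iff all indicators are favorable and 0 iff none is.
    """
    b = weights.as_array()
    if b.sum() <= 0:
        raise ValueError("sum of weights must be > 0")
    block = indicators[INDICATOR_COLUMNS].to_numpy(dtype=float)
    score = block @ b * (5.0 / b.sum())
    score = np.clip(score, 0.0, 5.0)  # guard float round-off at the 5.0 cap
    return pd.Series(score, index=indicators.index, name="weighted_lifestyle_score")


def attach_lifestyle(cohort: pd.DataFrame) -> pd.DataFrame:
    """Append indicator, score and category columns to a cohort table."""
    indicators = classify_factors(cohort)
    out = cohort.copy()
    for col in INDICATOR_COLUMNS:
        out[col] = indicators[col]
    out["lifestyle_score"] = composite_score(indicators)
    out["lifestyle_category"] = categorize(out["lifestyle_score"])
    out["unfavorable_count"] = 5.0 - out["lifestyle_score"]
    return out
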