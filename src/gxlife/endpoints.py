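"""Exclusion cascade and analysis-endpoint construction.

A participant can fail more than one exclusion criterion (e.g. missing both
BMI and outcome data), so the final analysis count removes the *union* of
the flagged sets; the ledger records per-criterion counts, pairwise
overlaps and the final n, and the inclusion-exclusion identity holds
exactly.

Endpoints:

* prevalent obesity — BMI >= 30 kg/m^2 at baseline (boundary inclusive);
* incident obesity — first post-enrollment record from any source, with
  non-cases administratively censored at the follow-up horizon (or earlier
  death/loss); events on or before enrollment are prevalent, not incident;
* BMI-threshold incidence — baseline BMI < 30 transitioning to any
  follow-up BMI >= 30, restricted to participants with follow-up
  measurements.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

OBESITY_BMI_CUTOFF = 30.0


@dataclass
class ExclusionLedger:
    """Bookkeeping for the exclusion cascade."""

    initial_n: int
    criterion_counts: dict[str, int] = field(default_factory=dict)
    pairwise_overlaps: dict[str, int] = field(default_factory=dict)
    excluded_union: int = 0
    final_n: int = 0

    def check_identity(self) -> bool:
        """final n == initial n - |union of excluded sets|, exactly."""
        return self.final_n == self.initial_n - self.excluded_union

    def to_json(self, path=None) -> str:
        payload = {
            "initial_n": self.initial_n,
            "criterion_counts": self.criterion_counts,
            "pairwise_overlaps": self.pairwise_overlaps,
            "excluded_union": self.excluded_union,
            "final_n": self.final_n,
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def apply_exclusions(cohort: pd.DataFrame,
                     criteria: dict[str, pd.Series] | None = None
                     ) -> tuple[pd.DataFrame, ExclusionLedger]:
    """Remove the union of flagged participants and account for it.

    Parameters
    ----------
    cohort
        The full cohort table.
    criteria
        Mapping of criterion name to a boolean mask over ``cohort`` rows
        (True = excluded). Defaults to the ``missing_bmi`` /
        ``missing_outcome`` flags when present, else to ``bmi`` being NaN.
    """
    if criteria is None:
        criteria = {}
        if "missing_bmi" in cohort.columns:
            criteria["missing_bmi"] = cohort["missing_bmi"].astype(bool)
        elif "bmi" in cohort.columns:
            criteria["missing_bmi"] = cohort["bmi"].isna()
        if "missing_outcome" in cohort.columns:
            criteria["missing_outcome"] = cohort["missing_outcome"].astype(bool)

    masks = {name: np.asarray(mask, dtype=bool) for name, mask in criteria.items()}
    for name, mask in masks.items():
        if mask.shape[0] != len(cohort):
            raise ValueError(f"criterion {name!r} mask length mismatch")

    union = np.zeros(len(cohort), dtype=bool)
    for mask in masks.values():
        union |= mask

    ledger = ExclusionLedger(initial_n=len(cohort))
    ledger.criterion_counts = {name: int(m.sum()) for name, m in masks.items()}
    ledger.pairwise_overlaps = {
        f"{a}&{b}": int((masks[a] & masks[b]).sum())
        for a, b in itertools.combinations(sorted(masks), 2)
    }
    ledger.excluded_union = int(union.sum())
    kept = cohort.loc[~union].copy()
    ledger.final_n = len(kept)
    assert ledger.check_identity()
    return kept, ledger


def prevalent_obesity(cohort: pd.DataFrame,
                      bmi_col: str = "bmi") -> pd.Series:
    """Baseline-obesity flag: BMI >= 30 kg/m^2, missing BMI -> missing flag."""
    bmi = cohort[bmi_col]
    flag = (bmi >= OBESITY_BMI_CUTOFF).astype(float)
    return flag.where(bmi.notna()).rename("prevalent_obesity_bmi")


def incident_obesity(cohort: pd.DataFrame,
                     source_time_cols: list[str] | None = None,
                     horizon_years: float | None = None,
                     death_col: str | None = None,
                     loss_col: str | None = None) -> pd.DataFrame:
    """Build incident-obesity records from per-source event times.

    ``source_time_cols`` hold years from enrollment to each source's first
    obesity record (NaN = no record in that source); the earliest source
    defines the case date. Non-cases are censored at the earliest of death,
    loss to follow-up and the administrative horizon. A non-positive event
    time marks the participant prevalent at enrollment (flagged
    ``prevalent_at_enroll``, not an incident case).
    """
    if source_time_cols is None:
        if "incident_obesity_time" not in cohort.columns:
            raise KeyError("no incident-obesity source columns found")
        earliest = cohort["incident_obesity_time"].where(
            cohort["incident_obesity_event"] == 1)
    else:
        earliest = cohort[source_time_cols].min(axis=1)

    censor = pd.Series(np.inf, index=cohort.index)
    for col in (death_col, loss_col):
        if col is not None and col in cohort.columns:
            censor = np.minimum(censor, cohort[col].fillna(np.inf))
    if horizon_years is not None:
        censor = np.minimum(censor, horizon_years)
    elif "incident_obesity_time" in cohort.columns:
        censor = np.minimum(censor, cohort["incident_obesity_time"].fillna(np.inf))
    if not np.isfinite(censor).all():
        raise ValueError("censoring time undefined: supply horizon_years")

    prevalent_at_enroll = earliest.notna() & (earliest <= 0)
    is_event = earliest.notna() & (earliest > 0) & (earliest <= censor)
    time = np.where(is_event, earliest, censor)

    out = pd.DataFrame(index=cohort.index)
    out["endpoint"] = "incident_obesity"
    out["event"] = is_event.astype(float)
    out["time"] = time
    out["prevalent_at_enroll"] = prevalent_at_enroll
    out.loc[prevalent_at_enroll, ["event", "time"]] = np.nan
    return out


def bmi_threshold_incidence(cohort: pd.DataFrame,
                            baseline_col: str = "bmi",
                            followup_cols: list[str] = ("bmi_followup",),
                            ) -> pd.Series:
    """Case flag for transitioning from BMI < 30 to any follow-up BMI >= 30.

    Eligibility (explicit, configurable): baseline BMI present and < 30,
    and at least one follow-up measurement present. Ineligible rows get a
    missing flag.
    """
    followup_cols = list(followup_cols)
    for col in followup_cols:
        if col not in cohort.columns:
            raise KeyError(f"missing follow-up BMI column {col!r}")
    baseline = cohort[baseline_col]
    fmax = cohort[followup_cols].max(axis=1)
    eligible = baseline.notna() & (baseline < OBESITY_BMI_CUTOFF) & fmax.notna()
    case = (fmax >= OBESITY_BMI_CUTOFF).astype(float)
    return case.where(eligible).rename("bmi_threshold_case")


def endpoint_long_format(cohort: pd.DataFrame,
                         endpoints: list[str]) -> pd.DataFrame:
    """Stack (participant_id, endpoint, event, time) in long format."""
    frames = []
    for name in endpoints:
        frames.append(pd.DataFrame({
            "participant_id": cohort["participant_id"],
            "endpoint": name,
            "event": cohort[f"{name}_event"],
            "time": cohort[f"{name}_time"],
        }))
    return pd.concat(frames, ignore_index=True)
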