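"""Polygenic-score standardization and quintile-based risk categories.

The polygenic score (PGS) arrives as one raw number per participant; it is
standardized to mean 0 / SD 1 and categorized into low (lowest quintile),
intermediate (quintiles 2-4) and high (highest quintile) genetic risk from
empirical percentile ranks. The same percentile machinery supplies the
top-20% flags used for the alternative adiposity indices (body fat %, waist
circumference, waist-to-hip ratio) and for the high-PGS carrier contrast.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

GENETIC_CATEGORY_ORDER = ["low", "intermediate", "high"]
LOW_PERCENTILE = 20.0
HIGH_PERCENTILE = 80.0


def standardize(raw_scores) -> pd.Series:
    """Standardize raw scores to mean 0 and sample SD 1 (ddof=1).

    Affine-invariant for positive scalings and idempotent. Raises on fewer
    than two distinct finite values (zero variance).
    """
    s = pd.Series(np.asarray(raw_scores, dtype=float))
    if hasattr(raw_scores, "index"):
        s.index = raw_scores.index
    finite = s.dropna()
    if finite.nunique() < 2:
        raise ValueError("standardize needs at least 2 distinct finite values")
    sd = finite.std(ddof=1)
    return ((s - finite.mean()) / sd).rename("pgs_z")


def percentile_ranks(values) -> pd.Series:
    """Empirical percentile in (0, 100] by the average-rank convention."""
    s = pd.Series(np.asarray(values, dtype=float))
    if hasattr(values, "index"):
        s.index = values.index
    if s.dropna().empty:
        raise ValueError("cannot rank an empty vector")
    pct = s.rank(method="average") / s.notna().sum() * 100.0
    return pct.rename("pgs_percentile")


def assign_categories(values) -> pd.DataFrame:
    """Assign percentile ranks and quintile-based genetic risk categories.

    low iff percentile <= 20, high iff percentile > 80, else intermediate.
    Rank-based, so raw and standardized scores give identical categories;
    a tied block falls entirely on the side holding its average rank.
    """
    pct = percentile_ranks(values)
    cat = pd.Series(
        np.where(pct <= LOW_PERCENTILE, "low",
                 np.where(pct > HIGH_PERCENTILE, "high", "intermediate")),
        index=pct.index, name="genetic_category",
    )
    cat = cat.where(pct.notna())
    cat = pd.Series(
        pd.Categorical(cat, categories=GENETIC_CATEGORY_ORDER),
        index=pct.index, name="genetic_category",
    )
    return pd.DataFrame({"pgs_percentile": pct, "genetic_category": cat})


def top_fraction_flag(values, fraction: float) -> pd.Series:
    """Flag the top ``fraction`` of the empirical distribution.

    Used for the top-20% adiposity-index endpoints and the high-PGS carrier
    group. Ties at the threshold are resolved by the average-rank rule, so
    the flag is deterministic and permutation-invariant.
    """
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must be in (0,1)")
    pct = percentile_ranks(values)
    flag = pct > (1.0 - fraction) * 100.0
    return flag.where(pct.notna()).astype("boolean").rename("top_flag")


def attach_genetic_risk(cohort: pd.DataFrame,
                        raw_col: str = "pgs_raw") -> pd.DataFrame:
    """Append ``pgs_z``, ``pgs_percentile`` and ``genetic_category``."""
    out = cohort.copy()
    out["pgs_z"] = standardize(cohort[raw_col])
    cats = assign_categories(out["pgs_z"])
    out["pgs_percentile"] = cats["pgs_percentile"]
    out["genetic_category"] = cats["genetic_category"]
    return out


def read_pgs_file(path) -> pd.DataFrame:
    """Read a two-column tab-delimited (participant_id, raw_pgs) file."""
    df = pd.read_csv(path, sep="\t")
    if df.shape[1] < 2:
        raise ValueError("PGS file must have participant_id and raw score columns")
    df.columns = ["participant_id", "pgs_raw"] + list(df.columns[2:])
    return df[["participant_id", "pgs_raw"]]
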