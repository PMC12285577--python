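"""Multiplicative and additive gene-lifestyle interaction.

Multiplicative interaction is the Wald test of a PGS x lifestyle product
term in the adjusted logistic model. Additive interaction is quantified by
the relative excess risk due to interaction,

    RERI = RR11 - RR10 - RR01 + 1,

with RR11/RR10/RR01 the relative risks (odds-ratio approximated) for
double, genetic-only and lifestyle-only exposure against the
double-unexposed corner, and the joint effect decomposed into attributable
proportions

    AP_G = (RR10 - 1) / (RR11 - 1)
    AP_L = (RR01 - 1) / (RR11 - 1)
    AP_I = RERI / (RR11 - 1),

which sum to 1 identically. Interaction analyses default to the
prevalent-obesity endpoint, which captures genetic influence accumulated
from before enrollment. Confidence intervals come from a nonparametric
participant-level bootstrap (percentile method) by default; a delta-method
alternative is provided for RERI.

The :class:`InteractionModel` front-end follows the Model/Results
convention: built from a cohort, ``fit()`` returns an
:class:`InteractionResults` with the decomposition, the multiplicative
p-value and a ``summary()`` table.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .models import FitResult, LogisticModel, covariate_preset


# mean of the top quintile of N(0,1): phi(z_{0.8}) / 0.2
_QUINTILE_TAIL_MEAN = float(stats.norm.pdf(stats.norm.ppf(0.8)) / 0.2)


@dataclass
class Contrast:
    """The four-corner contrast for the continuous-exposure RERI.

    Defaults: g0/g1 are the means of the bottom and top quintiles of a
    standard-normal PGS; l0/l1 are 0.5 and 4.5 unfavorable lifestyle
    points (the unfavorable direction of the 0-5 score).
    """

    g0: float = -_QUINTILE_TAIL_MEAN
    g1: float = _QUINTILE_TAIL_MEAN
    l0: float = 0.5
    l1: float = 4.5


def default_contrast() -> Contrast:
    return Contrast()


@dataclass
class InteractionDecomposition:
    """RERI and the three attributable proportions with their CIs."""

    rr11: float
    rr10: float
    rr01: float
    reri: float
    ap_g: float
    ap_l: float
    ap_i: float
    contrast: Contrast
    ci: dict = field(default_factory=dict)
    bootstrap_b: int | None = None
    bootstrap_seed: int | None = None
    notes: str = "odds ratios approximate relative risks"

    def to_dict(self) -> dict:
        return {
            "RR11": self.rr11, "RR10": self.rr10, "RR01": self.rr01,
            "RERI": self.reri,
            "AP_genetic": self.ap_g, "AP_lifestyle": self.ap_l,
            "AP_interaction": self.ap_i,
            "contrast": vars(self.contrast),
            "ci": self.ci,
            "bootstrap_B": self.bootstrap_b,
            "bootstrap_seed": self.bootstrap_seed,
            "notes": self.notes,
        }

    def to_row(self) -> pd.DataFrame:
        return pd.DataFrame([{
            "RR11": self.rr11, "RR10": self.rr10, "RR01": self.rr01,
            "RERI": self.reri, "AP_genetic": self.ap_g,
            "AP_lifestyle": self.ap_l, "AP_interaction": self.ap_i,
        }])


# ---------------------------------------------------------------------------
# point-estimate machinery
# ---------------------------------------------------------------------------

def reri_binary(rr11: float, rr10: float, rr01: float) -> float:
    """RERI from three relative risks against the double-unexposed group."""
    for name, rr in (("RR11", rr11), ("RR10", rr10), ("RR01", rr01)):
        if not rr > 0:
            raise ValueError(f"{name} must be > 0, got {rr}")
    return rr11 - rr10 - rr01 + 1.0


def decompose(rr11: float, rr10: float, rr01: float,
              contrast: Contrast | None = None) -> InteractionDecomposition:
    """Attributable-proportion decomposition of the joint effect."""
    reri = reri_binary(rr11, rr10, rr01)
    if rr11 <= 1.0:
        raise ValueError(
            f"decomposition undefined: joint relative risk RR11={rr11} <= 1")
    excess = rr11 - 1.0
    return InteractionDecomposition(
        rr11=rr11, rr10=rr10, rr01=rr01, reri=reri,
        ap_g=(rr10 - 1.0) / excess,
        ap_l=(rr01 - 1.0) / excess,
        ap_i=reri / excess,
        contrast=contrast or default_contrast(),
    )


def reri_continuous(fit: FitResult, contrast: Contrast | None = None,
                    pgs_term: str = "pgs_z",
                    lifestyle_term: str = "unfavorable_count",
                    product_term: str | None = None) -> InteractionDecomposition:
    """RERI/AP decomposition from a fitted continuous-exposure model.

    Evaluates the linear predictor at the four contrast corners
    (g0,l0), (g1,l0), (g0,l1), (g1,l1); shared covariate contributions
    cancel in the relative risks, so only the PGS, lifestyle and product
    coefficients enter.
    """
    contrast = contrast or default_contrast()
    if product_term is None:
        product_term = f"{pgs_term}:{lifestyle_term}"
    for term in (pgs_term, lifestyle_term, product_term):
        if term not in fit.params.index:
            raise KeyError(f"fit lacks required term {term!r}")
    bg = float(fit.params[pgs_term])
    bl = float(fit.params[lifestyle_term])
    bgl = float(fit.params[product_term])

    def eta(g, lv):
        return bg * g + bl * lv + bgl * g * lv

    e00 = eta(contrast.g0, contrast.l0)
    rr10 = float(np.exp(eta(contrast.g1, contrast.l0) - e00))
    rr01 = float(np.exp(eta(contrast.g0, contrast.l1) - e00))
    rr11 = float(np.exp(eta(contrast.g1, contrast.l1) - e00))
    if rr11 > 1.0:
        return decompose(rr11, rr10, rr01, contrast=contrast)
    # no excess joint risk: RERI is still defined, the AP shares are not
    return InteractionDecomposition(
        rr11=rr11, rr10=rr10, rr01=rr01,
        reri=reri_binary(rr11, rr10, rr01),
        ap_g=float("nan"), ap_l=float("nan"), ap_i=float("nan"),
        contrast=contrast,
        notes="odds ratios approximate relative risks; attributable "
              "proportions undefined (RR11 <= 1)")


def multiplicative_test(cohort: pd.DataFrame, *,
                        endpoint: str = "prevalent_obesity",
                        pgs_col: str = "pgs_z",
                        lifestyle_col: str = "unfavorable_count",
                        covariates: list[str] | None = None) -> FitResult:
    """Wald test of the PGS x lifestyle product term in the logistic model.

    Returns the full fit; the product-term p-value is exposed as
    ``result.p_interaction``.
    """
    df = cohort.copy()
    product = f"{pgs_col}:{lifestyle_col}"
    df[product] = df[pgs_col] * df[lifestyle_col]
    if df[product].nunique() <= 1:
        raise ValueError("product term is constant: interaction non-estimable")
    if covariates is None:
        covariates = covariate_preset("main", df, with_pgs=True)
    res = LogisticModel(df, outcome=endpoint,
                        covariates=[pgs_col, lifestyle_col, product] + covariates
                        ).fit()
    res.p_interaction = float(res.pvalues[product])
    return res


# ---------------------------------------------------------------------------
# uncertainty
# ---------------------------------------------------------------------------

def bootstrap_ci(cohort: pd.DataFrame, estimator, *, b: int = 1000,
                 seed: int = 0, level: float = 0.95,
                 max_failure_fraction: float = 0.05) -> dict:
    """Nonparametric participant-resampling percentile CIs.

    ``estimator(resampled_cohort)`` must return a mapping of quantity name
    to float. Resamples on which the estimator raises are counted; more
    than ``max_failure_fraction`` failures aborts.
    """
    if b < 100:
        raise ValueError("bootstrap needs B >= 100")
    rng = np.random.default_rng(seed)
    n = len(cohort)
    draws: dict[str, list[float]] = {}
    failures = 0
    for _ in range(b):
        idx = rng.integers(0, n, n)
        sample = cohort.iloc[idx].reset_index(drop=True)
        try:
            est = estimator(sample)
        except Exception:
            failures += 1
            continue
        for key, val in est.items():
            draws.setdefault(key, []).append(float(val))
    if failures > max_failure_fraction * b:
        raise RuntimeError(
            f"{failures}/{b} bootstrap resamples failed (> "
            f"{max_failure_fraction:.0%} allowed)")
    alpha = 1.0 - level
    out = {"_failures": failures, "_B": b, "_seed": seed}
    for key, vals in draws.items():
        lo, hi = np.quantile(vals, [alpha / 2, 1 - alpha / 2])
        out[key] = (float(lo), float(hi))
    return out


def reri_delta_ci(fit: FitResult, contrast: Contrast | None = None,
                  pgs_term: str = "pgs_z",
                  lifestyle_term: str = "unfavorable_count",
                  product_term: str | None = None,
                  level: float = 0.95) -> tuple[float, float]:
    """Delta-method CI for the continuous-exposure RERI."""
    contrast = contrast or default_contrast()
    if product_term is None:
        product_term = f"{pgs_term}:{lifestyle_term}"
    terms = [pgs_term, lifestyle_term, product_term]
    beta = fit.params[terms].to_numpy()
    cov = fit.cov.loc[terms, terms].to_numpy()

    g0, g1, l0, l1 = contrast.g0, contrast.g1, contrast.l0, contrast.l1

    def reri_of(bvec):
        bg, bl, bgl = bvec
        def eta(g, lv):
            return bg * g + bl * lv + bgl * g * lv
        e00 = eta(g0, l0)
        return (np.exp(eta(g1, l1) - e00) - np.exp(eta(g1, l0) - e00)
                - np.exp(eta(g0, l1) - e00) + 1.0)

    eps = 1e-6
    grad = np.zeros(3)
    for i in range(3):
        up, dn = beta.copy(), beta.copy()
        up[i] += eps
        dn[i] -= eps
        grad[i] = (reri_of(up) - reri_of(dn)) / (2 * eps)
    var = float(grad @ cov @ grad)
    zcrit = stats.norm.ppf(0.5 + level / 2)
    point = reri_of(beta)
    half = zcrit * np.sqrt(var)
    return float(point - half), float(point + half)


# ---------------------------------------------------------------------------
# Model/Results front-end
# ---------------------------------------------------------------------------

class InteractionResults:
    """Joint multiplicative + additive interaction results."""

    def __init__(self, decomposition: InteractionDecomposition,
                 multiplicative_fit: FitResult, endpoint: str):
        self.decomposition = decomposition
        self.multiplicative_fit = multiplicative_fit
        self.p_interaction = multiplicative_fit.p_interaction
        self.endpoint = endpoint

    def summary(self) -> pd.DataFrame:
        d = self.decomposition
        rows = [
            ("RERI", d.reri),
            ("AP_genetic", d.ap_g),
            ("AP_lifestyle", d.ap_l),
            ("AP_interaction", d.ap_i),
            ("RR11", d.rr11),
            ("RR10", d.rr10),
            ("RR01", d.rr01),
            ("p_interaction", self.p_interaction),
        ]
        out = pd.DataFrame(rows, columns=["quantity", "value"]).set_index("quantity")
        for q in ("RERI", "AP_genetic", "AP_lifestyle", "AP_interaction"):
            if q in d.ci:
                out.loc[q, "ci_low"], out.loc[q, "ci_high"] = d.ci[q]
        return out


class InteractionModel:
    """Gene-lifestyle interaction analysis on one endpoint.

    Built from a cohort carrying ``pgs_z`` and ``unfavorable_count``;
    ``fit()`` runs the multiplicative product-term test and the
    continuous-exposure RERI/AP decomposition, optionally with bootstrap
    CIs.
    """

    def __init__(self, cohort: pd.DataFrame, *,
                 endpoint: str = "prevalent_obesity",
                 contrast: Contrast | None = None,
                 covariates: list[str] | None = None):
        self.cohort = cohort
        self.endpoint = endpoint
        self.contrast = contrast or default_contrast()
        self.covariates = covariates

    def _point_fit(self, data: pd.DataFrame) -> FitResult:
        return multiplicative_test(
            data, endpoint=self.endpoint, covariates=self.covariates)

    def fit(self, *, bootstrap_b: int = 0, seed: int = 0) -> InteractionResults:
        mfit = self._point_fit(self.cohort)
        dec = reri_continuous(mfit, self.contrast)
        if bootstrap_b:
            def estimator(sample):
                f = self._point_fit(sample)
                d = reri_continuous(f, self.contrast)
                return {"RERI": d.reri, "AP_genetic": d.ap_g,
                        "AP_lifestyle": d.ap_l, "AP_interaction": d.ap_i}
            cis = bootstrap_ci(self.cohort, estimator, b=bootstrap_b, seed=seed)
            dec.ci = {k: v for k, v in cis.items() if not k.startswith("_")}
            dec.bootstrap_b = bootstrap_b
            dec.bootstrap_seed = seed
        return InteractionResults(dec, mfit, self.endpoint)
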