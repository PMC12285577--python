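"""Regression contracts and absolute-risk prediction.

Model classes follow the Model/Results convention: a model object is built
from a cohort DataFrame and a design specification; ``fit()`` returns a
results object carrying the coefficient vector, covariance matrix, Wald
inference and a ``summary()`` table.

* :class:`CoxModel` — proportional-hazards partial likelihood (Breslow tie
  handling by default, Efron optional) for incident endpoints; hazard
  ratios are ``exp(coef)``. The Breslow baseline cumulative hazard at
  covariates = 0 supports absolute-risk prediction.
* :class:`LogisticModel` — maximum-likelihood logistic regression for
  prevalent endpoints; odds ratios are ``exp(coef)``.
* :func:`joint_category_grid` — the 3x3 genetic-risk x lifestyle grid from
  a single model with eight indicator contrasts against the low-genetic /
  healthy-lifestyle reference cell.
* :func:`isolated_effect` — one domain's category effects adjusted for the
  other domain plus covariates, with a trend p-value from the continuous
  score.
* :func:`absolute_risk_by_age` / :func:`risk_gradient_curve` — predicted
  probability of the endpoint by a target age (default 75) as
  ``1 - S0(t*)^exp(eta)``, evaluated across polygenic-score percentiles
  for the healthy and poor lifestyle groups.

The timescale is follow-up time with enrollment age as a covariate; the
target-age conversion uses ``t* = target_age - mean enrollment age``.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

# reference levels for categorical covariates (first level = baseline)
DEFAULT_REFERENCES = {
    "sex": "female",
    "lifestyle_category": "healthy",
    "genetic_category": "low",
    "deprivation_tertile": "low",
    "smoking_status": "never",
}

_MAIN_COVARIATES = [
    "age_enroll", "sex_male", "education_high", "deprivation_tertile",
    "smoking_status", "diabetes", "depression", "cushing",
    "hypothyroidism", "pcos", "weight_gain_med",
]


def covariate_preset(name: str, cohort: pd.DataFrame,
                     with_pgs: bool = False) -> list[str]:
    """Named covariate sets.

    ``"main"`` — the full adjustment list (age, sex, education, deprivation,
    smoking, diabetes, weight-affecting conditions, weight-gain medication),
    plus genotyping array and the first 10 principal components when the
    model includes the polygenic score. ``"risk-curve"`` — enrollment age,
    sex and the first four principal components.
    """
    if name == "main":
        cols = [c for c in _MAIN_COVARIATES if c in cohort.columns]
        if with_pgs:
            cols += [c for c in ["genotyping_array"] if c in cohort.columns]
            cols += [f"pc{k}" for k in range(1, 11) if f"pc{k}" in cohort.columns]
        return cols
    if name == "risk-curve":
        cols = [c for c in ("age_enroll", "sex_male") if c in cohort.columns]
        cols += [f"pc{k}" for k in range(1, 5) if f"pc{k}" in cohort.columns]
        return cols
    raise ValueError(f"unknown covariate preset {name!r}")


def build_design(data: pd.DataFrame, covariates: list[str],
                 references: dict | None = None) -> pd.DataFrame:
    """Expand covariates into a numeric design matrix (no intercept).

    Categorical/object columns become indicator columns ``col[level]`` for
    every non-reference level; numeric columns pass through as float.
    """
    refs = dict(DEFAULT_REFERENCES)
    if references:
        refs.update(references)
    pieces = []
    for col in covariates:
        if col not in data.columns:
            raise KeyError(f"design column {col!r} not in data")
        s = data[col]
        if isinstance(s.dtype, pd.CategoricalDtype) or s.dtype == object:
            levels = (list(s.cat.categories)
                      if isinstance(s.dtype, pd.CategoricalDtype)
                      else sorted(s.dropna().unique()))
            ref = refs.get(col, levels[0])
            for level in levels:
                if level == ref:
                    continue
                pieces.append(pd.Series(
                    (s == level).astype(float).where(s.notna()),
                    name=f"{col}[{level}]"))
        else:
            pieces.append(s.astype(float).rename(col))
    if not pieces:
        return pd.DataFrame(index=data.index)
    return pd.concat(pieces, axis=1)


# ---------------------------------------------------------------------------
# results containers
# ---------------------------------------------------------------------------

@dataclass
class FitResult:
    """Coefficients, covariance and Wald inference for one fitted model."""

    params: pd.Series
    cov: pd.DataFrame
    loglik: float
    n: int
    n_events: int | None
    family: str  # "cox" or "logistic"
    formula: str
    references: dict = field(default_factory=dict)
    dropped_constant: list[str] = field(default_factory=list)

    @property
    def se(self) -> pd.Series:
        return pd.Series(np.sqrt(np.diag(self.cov)), index=self.params.index,
                         name="se")

    @property
    def pvalues(self) -> pd.Series:
        z = self.params / self.se
        return pd.Series(2 * stats.norm.sf(np.abs(z)), index=self.params.index,
                         name="p")

    def conf_int(self, level: float = 0.95) -> pd.DataFrame:
        zcrit = stats.norm.ppf(0.5 + level / 2)
        lo = self.params - zcrit * self.se
        hi = self.params + zcrit * self.se
        return pd.DataFrame({"ci_low": lo, "ci_high": hi})

    def ratios(self) -> pd.Series:
        """exp(coef): hazard ratios (Cox) or odds ratios (logistic)."""
        name = "HR" if self.family == "cox" else "OR"
        return np.exp(self.params).rename(name)

    def summary(self, level: float = 0.95) -> pd.DataFrame:
        ci = np.exp(self.conf_int(level))
        out = pd.DataFrame({
            "estimate": self.params,
            "se": self.se,
            self.ratios().name: self.ratios(),
            "ci_low": ci["ci_low"],
            "ci_high": ci["ci_high"],
            "p": self.pvalues,
        })
        out.index.name = "term"
        return out

    def fit_hash(self) -> str:
        payload = self.params.to_json().encode()
        return hashlib.sha256(payload).hexdigest()[:16]

    def to_tsv(self, path) -> None:
        self.summary().to_csv(path, sep="\t")


class CoxResults(FitResult):
    """Cox fit plus the training data needed for baseline-risk prediction."""

    def __init__(self, *args, training_frame: pd.DataFrame | None = None,
                 duration_col: str = "time", event_col: str = "event",
                 design_columns: list[str] | None = None, **kwargs):
        super().__init__(*args, **kwargs)
        self._training = training_frame
        self._duration_col = duration_col
        self._event_col = event_col
        self._design_columns = design_columns or list(self.params.index)
        self._baseline = None

    def linear_predictor(self, design: pd.DataFrame) -> np.ndarray:
        X = design[self._design_columns].to_numpy(dtype=float)
        return X @ self.params.to_numpy()

    def baseline_cumulative_hazard(self) -> pd.DataFrame:
        """Breslow baseline cumulative hazard at covariates = 0.

        ``H0(t) = sum over event times t_j <= t of d_j / sum over the risk
        set at t_j of exp(x beta)`` — a nonnegative, nondecreasing step
        function with jumps only at observed event times.
        """
        if self._baseline is None:
            if self._training is None:
                raise ValueError("results carry no training data")
            self._baseline = breslow_baseline(
                self._training[self._duration_col].to_numpy(dtype=float),
                self._training[self._event_col].to_numpy(dtype=float),
                self.linear_predictor(self._training),
            )
        return self._baseline

    def baseline_survival_at(self, t: float) -> float:
        """Baseline survival S0(t), extended beyond observed follow-up.

        Within follow-up this is the Breslow step function. A target age
        often lies beyond the administrative censoring horizon; there the
        cumulative hazard is extended at the average observed baseline
        rate, H0(t) = H0(t_max) * t / t_max — exact when the baseline
        hazard is constant.
        """
        base = self.baseline_cumulative_hazard()
        if base.empty:
            return 1.0
        t_max = float(base["time"].iloc[-1])
        if t <= t_max:
            past = base.loc[base["time"] <= t, "cumhaz"]
            h0 = 0.0 if past.empty else float(past.iloc[-1])
        else:
            h0 = float(base["cumhaz"].iloc[-1]) * t / t_max
        return float(np.exp(-h0))

    def covariate_means(self) -> pd.Series:
        return self._training[self._design_columns].mean()


def breslow_baseline(durations: np.ndarray, events: np.ndarray,
                     eta: np.ndarray) -> pd.DataFrame:
    """Breslow estimator of the baseline cumulative hazard at x = 0."""
    order = np.argsort(durations, kind="stable")
    t = durations[order]
    d = events[order].astype(bool)
    w = np.exp(eta[order])
    # risk-set denominator: sum of w over subjects with time >= t_j
    rev_cum = np.cumsum(w[::-1])[::-1]
    event_times, idx = np.unique(t[d], return_index=False), None
    rows = []
    cum = 0.0
    for tj in event_times:
        dj = int(((t == tj) & d).sum())
        denom = rev_cum[np.searchsorted(t, tj, side="left")]
        cum += dj / denom
        rows.append((tj, cum))
    return pd.DataFrame(rows, columns=["time", "cumhaz"])


# ---------------------------------------------------------------------------
# model classes
# ---------------------------------------------------------------------------

class CoxModel:
    """Proportional-hazards model for an incident endpoint.

    Parameters
    ----------
    data
        Cohort rows; complete cases on the design, duration and event
        columns are used.
    duration_col, event_col
        Follow-up time (years) and 0/1 event indicator.
    covariates
        Columns to enter the design; categoricals expand to indicators.
    """

    def __init__(self, data: pd.DataFrame, duration_col: str, event_col: str,
                 covariates: list[str], references: dict | None = None):
        design = build_design(data, covariates, references)
        frame = pd.concat([data[[duration_col, event_col]], design], axis=1)
        frame = frame.dropna()
        if len(frame) == 0:
            raise ValueError("no complete-case rows for Cox fit")
        if (frame[duration_col] < 0).any():
            raise ValueError("negative durations")
        self.data = frame
        self.duration_col = duration_col
        self.event_col = event_col
        self.design_columns = list(design.columns)
        self.references = references or {}
        self.formula = f"{event_col}/{duration_col} ~ " + " + ".join(covariates)

    def fit(self, ties: str = "breslow") -> CoxResults:
        import warnings

        from statsmodels.duration.hazard_regression import PHReg
        from statsmodels.tools.sm_exceptions import ConvergenceWarning

        frame = self.data
        n_events = int(frame[self.event_col].sum())
        if n_events == 0:
            raise ValueError("Cox fit requires at least one event")

        cols = list(self.design_columns)
        constant = [c for c in cols if frame[c].nunique() <= 1]
        # rare binary columns destabilize the partial likelihood (separation
        # or a lone carrier dominating a risk set): pin at 0 rather than fail
        events_mask = frame[self.event_col] == 1
        for c in cols:
            if c in constant:
                continue
            vals = frame[c]
            if set(vals.unique()) <= {0.0, 1.0}:
                minority = int(min(vals.sum(), (1 - vals).sum()))
                if minority == 0 or minority >= 0.01 * len(frame):
                    continue
                ev = vals[events_mask]
                separated = ev.sum() == 0 or (1 - ev).sum() == 0
                if minority < 5 or separated:
                    constant.append(c)
        active = [c for c in cols if c not in constant]
        if not active:
            raise ValueError("design has no varying covariate columns")

        X = frame[active].to_numpy(dtype=float)
        mod = PHReg(frame[self.duration_col].to_numpy(dtype=float), X,
                    status=frame[self.event_col].to_numpy(dtype=float),
                    ties=ties)
        try:
            with warnings.catch_warnings():
                # the optimizer's maxiter flag can trip even at a stationary
                # point; convergence is re-checked below via the score norm
                warnings.simplefilter("ignore", ConvergenceWarning)
                res = mod.fit(disp=False)
        except np.linalg.LinAlgError as exc:
            raise ValueError(f"Cox design is singular: {exc}") from exc
        grad = np.linalg.norm(mod.score(res.params))
        scale = max(1.0, np.linalg.norm(res.params))
        if not np.all(np.isfinite(res.params)) or grad > 1e-3 * scale * n_events:
            raise ValueError(f"Cox fit did not converge (gradient norm {grad:.3g})")

        params = pd.Series(0.0, index=cols, name="coef")
        cov = pd.DataFrame(0.0, index=cols, columns=cols)
        params[active] = res.params
        cov.loc[active, active] = res.cov_params()
        for c in constant:
            cov.loc[c, c] = np.nan  # pinned, not estimated

        return CoxResults(
            params=params, cov=cov, loglik=float(mod.loglike(res.params)),
            n=len(frame), n_events=n_events, family="cox",
            formula=self.formula, references=self.references,
            dropped_constant=constant,
            training_frame=frame, duration_col=self.duration_col,
            event_col=self.event_col, design_columns=cols,
        )


class LogisticModel:
    """Maximum-likelihood logistic regression for a prevalent endpoint."""

    def __init__(self, data: pd.DataFrame, outcome: str,
                 covariates: list[str], references: dict | None = None):
        design = build_design(data, covariates, references)
        frame = pd.concat([data[[outcome]], design], axis=1).dropna()
        if len(frame) == 0:
            raise ValueError("no complete-case rows for logistic fit")
        y = frame[outcome]
        if not set(np.unique(y)) <= {0.0, 1.0}:
            raise ValueError("outcome must be binary 0/1")
        if y.nunique() < 2:
            raise ValueError("both outcome classes must be present")
        self.data = frame
        self.outcome = outcome
        self.design_columns = list(design.columns)
        self.references = references or {}
        self.formula = f"{outcome} ~ " + " + ".join(covariates)

    def fit(self) -> FitResult:
        import warnings

        import statsmodels.api as sm
        from statsmodels.tools.sm_exceptions import ConvergenceWarning

        frame = self.data
        cols = list(self.design_columns)
        constant = [c for c in cols if frame[c].nunique() <= 1]
        # a rare binary covariate whose carriers all share one outcome has
        # an unbounded MLE (quasi-separation): pin it at 0
        y = frame[self.outcome]
        for c in cols:
            if c in constant:
                continue
            vals = frame[c]
            if set(vals.unique()) <= {0.0, 1.0}:
                minority_side = vals == (1.0 if vals.mean() < 0.5 else 0.0)
                if (minority_side.sum() < 0.01 * len(frame)
                        and y[minority_side].nunique() < 2):
                    constant.append(c)
        active = [c for c in cols if c not in constant]

        X = sm.add_constant(frame[active].to_numpy(dtype=float), has_constant="add")
        mod = sm.Logit(frame[self.outcome].to_numpy(dtype=float), X)
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", ConvergenceWarning)
                warnings.simplefilter("ignore", RuntimeWarning)
                try:
                    from statsmodels.tools.sm_exceptions import (
                        PerfectSeparationWarning)
                    warnings.simplefilter("ignore", PerfectSeparationWarning)
                except ImportError:
                    pass
                res = mod.fit(disp=0, maxiter=200)
        except Exception as exc:  # statsmodels PerfectSeparation*, LinAlgError
            raise ValueError(f"logistic fit failed: {exc}") from exc
        grad = np.linalg.norm(mod.score(res.params))
        if not np.all(np.isfinite(res.params)) or grad > 1e-3 * len(frame):
            raise ValueError("logistic fit produced non-finite or unstable "
                             "estimates (possible separation)")

        names = ["intercept"] + active
        params = pd.Series(res.params, index=names, name="coef")
        cov = pd.DataFrame(res.cov_params(), index=names, columns=names)
        for c in constant:  # pinned at 0, not estimated
            params[c] = 0.0
            cov.loc[c, :] = 0.0
            cov.loc[:, c] = 0.0
            cov.loc[c, c] = np.nan

        order = ["intercept"] + cols
        return FitResult(
            params=params.reindex(order), cov=cov.reindex(index=order, columns=order),
            loglik=float(res.llf), n=len(frame),
            n_events=int(frame[self.outcome].sum()), family="logistic",
            formula=self.formula, references=self.references,
            dropped_constant=constant,
        )


def fit_cox(data: pd.DataFrame, duration_col: str, event_col: str,
            covariates: list[str], ties: str = "breslow",
            references: dict | None = None) -> CoxResults:
    return CoxModel(data, duration_col, event_col, covariates,
                    references).fit(ties=ties)


def fit_logistic(data: pd.DataFrame, outcome: str, covariates: list[str],
                 references: dict | None = None) -> FitResult:
    return LogisticModel(data, outcome, covariates, references).fit()


# ---------------------------------------------------------------------------
# joint grid and isolated effects
# ---------------------------------------------------------------------------

GENETIC_LEVELS = ["low", "intermediate", "high"]
LIFESTYLE_LEVELS = ["healthy", "intermediate", "poor"]


def joint_category_grid(cohort: pd.DataFrame, *,
                        endpoint: str = "incident_obesity",
                        family: str = "cox",
                        covariates: list[str] | None = None) -> pd.DataFrame:
    """The 3x3 genetic-risk x lifestyle grid against the reference cell.

    Fits one model with eight joint-category indicators (low genetic risk /
    healthy lifestyle as reference) plus covariates and returns a tidy
    9-row table with HR (or OR), CI, p, and cell counts; empty cells are
    flagged non-estimable.
    """
    df = cohort.copy()
    if covariates is None:
        covariates = covariate_preset("main", df, with_pgs=False)

    cells = [(g, l) for g in GENETIC_LEVELS for l in LIFESTYLE_LEVELS]
    ref = ("low", "healthy")
    g = df["genetic_category"].astype(str)
    l = df["lifestyle_category"].astype(str)
    valid = g.isin(GENETIC_LEVELS) & l.isin(LIFESTYLE_LEVELS)

    indicator_cols = []
    for cell in cells:
        if cell == ref:
            continue
        col = f"cell[{cell[0]}/{cell[1]}]"
        df[col] = np.where(valid, ((g == cell[0]) & (l == cell[1])).astype(float),
                           np.nan)
        indicator_cols.append(col)

    counts = {cell: int(((g == cell[0]) & (l == cell[1])).sum()) for cell in cells}
    estimable = {cell: cell == ref or counts[cell] > 0 for cell in cells}
    usable = [f"cell[{c[0]}/{c[1]}]" for c in cells
              if c != ref and estimable[c]]

    if family == "cox":
        res = fit_cox(df, f"{endpoint}_time", f"{endpoint}_event",
                      usable + covariates)
    elif family == "logistic":
        res = fit_logistic(df, endpoint, usable + covariates)
    else:
        raise ValueError("family must be 'cox' or 'logistic'")

    label = "HR" if family == "cox" else "OR"
    summ = res.summary()
    rows = []
    for cell in cells:
        col = f"cell[{cell[0]}/{cell[1]}]"
        row = {"genetic_category": cell[0], "lifestyle_category": cell[1],
               "n": counts[cell], "reference": cell == ref,
               "estimable": estimable[cell]}
        if cell == ref:
            row.update({label: 1.0, "ci_low": np.nan, "ci_high": np.nan,
                        "p": np.nan})
        elif estimable[cell]:
            row.update({label: summ.loc[col, label],
                        "ci_low": summ.loc[col, "ci_low"],
                        "ci_high": summ.loc[col, "ci_high"],
                        "p": summ.loc[col, "p"]})
        else:
            row.update({label: np.nan, "ci_low": np.nan, "ci_high": np.nan,
                        "p": np.nan})
        rows.append(row)
    grid = pd.DataFrame(rows)
    grid.attrs["fit"] = res
    return grid


def isolated_effect(cohort: pd.DataFrame, *, domain: str,
                    endpoint: str = "incident_obesity",
                    family: str = "cox",
                    covariates: list[str] | None = None) -> FitResult:
    """One domain's category effects adjusted for the other domain.

    ``domain="genetic"`` estimates genetic-risk category effects adjusted
    for lifestyle categories and covariates (and vice versa). The result
    gains a ``trend_p`` attribute from refitting with the domain's
    continuous score (``pgs_z`` or ``lifestyle_score``) in place of its
    categories.
    """
    if domain not in ("genetic", "lifestyle"):
        raise ValueError("domain must be 'genetic' or 'lifestyle'")
    if covariates is None:
        covariates = covariate_preset("main", cohort, with_pgs=True)

    own = "genetic_category" if domain == "genetic" else "lifestyle_category"
    other = "lifestyle_category" if domain == "genetic" else "genetic_category"
    trend_col = "pgs_z" if domain == "genetic" else "lifestyle_score"

    def _fit(cols):
        if family == "cox":
            return fit_cox(cohort, f"{endpoint}_time", f"{endpoint}_event", cols)
        if family == "logistic":
            return fit_logistic(cohort, endpoint, cols)
        raise ValueError("family must be 'cox' or 'logistic'")

    res = _fit([own, other] + covariates)
    trend = _fit([trend_col, other] + covariates)
    res.trend_p = float(trend.pvalues[trend_col])
    return res


# ---------------------------------------------------------------------------
# absolute risk by target age
# ---------------------------------------------------------------------------

def fit_risk_model(cohort: pd.DataFrame,
                   endpoint: str = "incident_obesity") -> CoxResults:
    """Cox model powering the risk-by-age curves.

    Design: lifestyle-category indicators (healthy reference), continuous
    standardized PGS, enrollment age, sex and the first four principal
    components.
    """
    covs = ["lifestyle_category", "pgs_z"] + covariate_preset("risk-curve", cohort)
    return fit_cox(cohort, f"{endpoint}_time", f"{endpoint}_event", covs)


def absolute_risk_by_age(fit: CoxResults, *, group: str,
                         pgs_percentile: float,
                         target_age: float = 75.0) -> float:
    """Predicted probability (%) of the endpoint by ``target_age``.

    ``1 - S0(t*)^exp(eta)`` with S0 the Breslow baseline survival,
    ``t* = target_age - mean enrollment age``, and eta the linear predictor
    at the requested lifestyle group, the PGS value of the requested
    percentile (standard-normal quantile), and the means of the remaining
    covariates.
    """
    if not 0.0 < pgs_percentile < 100.0:
        raise ValueError("pgs_percentile must be in (0, 100)")
    means = fit.covariate_means()
    if "age_enroll" not in means.index:
        raise ValueError("risk model must include enrollment age")
    t_star = target_age - float(means["age_enroll"])
    if t_star <= 0:
        raise ValueError(f"target age {target_age} precedes mean enrollment age")

    x = means.copy()
    for col in x.index:  # lifestyle group indicators
        if col.startswith("lifestyle_category["):
            x[col] = 1.0 if col == f"lifestyle_category[{group}]" else 0.0
    if group not in LIFESTYLE_LEVELS:
        raise ValueError(f"unknown lifestyle group {group!r}")
    if "pgs_z" in x.index:
        x["pgs_z"] = stats.norm.ppf(pgs_percentile / 100.0)

    eta = float(x.to_numpy() @ fit.params.to_numpy())
    s0 = fit.baseline_survival_at(t_star)
    return (1.0 - s0 ** np.exp(eta)) * 100.0


def risk_gradient_curve(fit: CoxResults,
                        percentiles=None,
                        target_age: float = 75.0) -> pd.DataFrame:
    """Healthy vs poor risk-by-age curves over a PGS-percentile grid.

    Returns a tidy frame (percentile, healthy_pct, poor_pct, difference)
    where ``difference = poor - healthy`` in percentage units.
    """
    if percentiles is None:
        percentiles = np.arange(1, 100)
    rows = []
    for p in percentiles:
        healthy = absolute_risk_by_age(fit, group="healthy", pgs_percentile=p,
                                       target_age=target_age)
        poor = absolute_risk_by_age(fit, group="poor", pgs_percentile=p,
                                    target_age=target_age)
        rows.append((p, healthy, poor, poor - healthy))
    return pd.DataFrame(rows, columns=["percentile", "healthy_pct", "poor_pct",
                                       "difference"])
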