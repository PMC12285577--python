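"""Simulation configuration for the synthetic obesity cohort.

The defaults encode the study conditions the analysis pipeline assumes: a
standardized polygenic score (PGS, mean 0 / SD 1), five binary lifestyle
factors at the favorable-fraction prevalences observed among non-obese
participants (physical activity 32.4%, diet 36.9%, alcohol 67.3%, sedentary
behavior 33.2%, sleep 89.4%), prevalent obesity from a logistic liability
with a gene-lifestyle product term, and incident obesity plus 20
obesity-related morbidity (ORM) endpoints from proportional-hazards models
with BMI-mediated genetic effects and administrative censoring.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from typing import Sequence

import yaml

#: Canonical factor order used for prevalence vectors throughout the package.
FACTOR_NAMES = ("physical_activity", "diet", "alcohol", "sedentary", "sleep")

#: Favorable-fraction prevalences among non-obese participants.
DEFAULT_PREVALENCES = (0.324, 0.369, 0.673, 0.332, 0.894)

N_ORM_ENDPOINTS = 20


@dataclass
class BMIModel:
    """Linear model for baseline BMI (kg/m^2)."""

    intercept: float = 26.0
    per_sd_pgs: float = 1.6
    per_factor: float = 0.5  # per unfavorable lifestyle factor
    noise_sd: float = 3.5

    def validate(self) -> None:
        if not self.noise_sd > 0:
            raise ValueError("bmi_model.noise_sd must be > 0")
        for name in ("intercept", "per_sd_pgs", "per_factor"):
            _require_finite(getattr(self, name), f"bmi_model.{name}")


@dataclass
class HazardSpec:
    """Exponential-baseline proportional-hazards model for one endpoint.

    ``baseline_rate`` (events/person-year) applies at BMI 25 kg/m^2, PGS 0
    and zero unfavorable lifestyle factors; ``per_bmi`` is the log-hazard
    per kg/m^2 above 25, ``per_sd_pgs`` the direct (non-BMI-mediated)
    log-hazard per SD of PGS, ``per_factor`` the log-hazard per unfavorable
    lifestyle factor.
    """

    name: str
    baseline_rate: float
    per_bmi: float = 0.0
    per_sd_pgs: float = 0.0
    per_factor: float = 0.0

    def validate(self) -> None:
        if not self.baseline_rate > 0:
            raise ValueError(f"hazard {self.name}: baseline_rate must be > 0")
        for attr in ("baseline_rate", "per_bmi", "per_sd_pgs", "per_factor"):
            _require_finite(getattr(self, attr), f"hazard {self.name}.{attr}")


@dataclass
class CovariateDists:
    """Enrollment covariate distributions."""

    age_min: float = 40.0
    age_max: float = 70.0
    female_fraction: float = 0.54
    n_pcs: int = 10
    pc_scale: float = 1.0

    def validate(self) -> None:
        if not self.age_min < self.age_max:
            raise ValueError("age_min must be < age_max")
        if not 0.0 < self.female_fraction < 1.0:
            raise ValueError("female_fraction must be in (0,1)")
        if self.n_pcs < 1:
            raise ValueError("n_pcs must be >= 1")
        if not self.pc_scale > 0:
            raise ValueError("pc_scale must be > 0")


def _default_orm_hazards() -> list[HazardSpec]:
    # 15 endpoints causally downstream of adiposity, 5 null ones: the scan
    # over all 20 should replicate the adiposity-driven subset only.
    specs = []
    for i in range(1, N_ORM_ENDPOINTS + 1):
        per_bmi = 0.08 if i <= 15 else 0.0
        specs.append(
            HazardSpec(name=f"orm_{i:02d}", baseline_rate=0.003, per_bmi=per_bmi)
        )
    return specs


@dataclass
class SimulationConfig:
    """Full generative configuration for one synthetic cohort."""

    n_participants: int = 20_000
    seed: int = 0
    factor_prevalences: Sequence[float] = DEFAULT_PREVALENCES
    # Prevalent-obesity logistic liability (log-odds scale).
    beta0: float = -2.0
    beta_pgs: float = 0.55  # per SD of PGS
    beta_lifestyle: float = 0.27  # per unfavorable factor
    beta_interaction: float = 0.05  # per (SD x unfavorable factor)
    bmi_model: BMIModel = field(default_factory=BMIModel)
    incident_obesity_hazard: HazardSpec = field(
        default_factory=lambda: HazardSpec(
            name="incident_obesity",
            baseline_rate=1.4e-3,
            per_bmi=0.0,
            per_sd_pgs=0.22,
            per_factor=0.11,
        )
    )
    orm_hazards: list[HazardSpec] = field(default_factory=_default_orm_hazards)
    censor_years: float = 11.55
    missing_bmi_rate: float = 0.0032
    missing_outcome_rate: float = 0.0001
    covariate_dists: CovariateDists = field(default_factory=CovariateDists)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.n_participants < 0:
            raise ValueError("n_participants must be >= 0")
        if len(self.factor_prevalences) != 5:
            raise ValueError("factor_prevalences must have exactly 5 entries")
        for p, name in zip(self.factor_prevalences, FACTOR_NAMES):
            if not 0.0 < p < 1.0:
                raise ValueError(f"prevalence for {name} must be in (0,1), got {p}")
        for attr in ("beta0", "beta_pgs", "beta_lifestyle", "beta_interaction"):
            _require_finite(getattr(self, attr), attr)
        if not self.censor_years > 0:
            raise ValueError("censor_years must be > 0")
        for attr in ("missing_bmi_rate", "missing_outcome_rate"):
            rate = getattr(self, attr)
            if not 0.0 <= rate <= 1.0:
                raise ValueError(f"{attr} must be in [0,1]")
        self.bmi_model.validate()
        self.incident_obesity_hazard.validate()
        for spec in self.orm_hazards:
            spec.validate()
        self.covariate_dists.validate()

    # -- serialization ----------------------------------------------------

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        if "bmi_model" in d and isinstance(d["bmi_model"], dict):
            d["bmi_model"] = BMIModel(**d["bmi_model"])
        if "incident_obesity_hazard" in d and isinstance(
            d["incident_obesity_hazard"], dict
        ):
            d["incident_obesity_hazard"] = HazardSpec(**d["incident_obesity_hazard"])
        if "orm_hazards" in d:
            d["orm_hazards"] = [
                HazardSpec(**h) if isinstance(h, dict) else h for h in d["orm_hazards"]
            ]
        if "covariate_dists" in d and isinstance(d["covariate_dists"], dict):
            d["covariate_dists"] = CovariateDists(**d["covariate_dists"])
        if "factor_prevalences" in d:
            d["factor_prevalences"] = tuple(d["factor_prevalences"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ValueError(f"config file {path} must contain a mapping")
        try:
            return cls.from_dict(data)
        except TypeError as exc:
            raise ValueError(f"invalid config key: {exc}") from exc

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(_jsonable(self.to_dict()), fh, sort_keys=False)

    def config_hash(self) -> str:
        payload = json.dumps(_jsonable(self.to_dict()), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def calibrated_interaction_config(
        ap_genetic: float = 0.566, ap_lifestyle: float = 0.252,
        rr11: float = 2.0, **overrides) -> SimulationConfig:
    """Configuration whose true-model joint-effect decomposition is fixed.

    Solves the liability coefficients so that, at the default four-corner
    contrast (quintile-mean PGS values, 0.5/4.5 unfavorable lifestyle
    points), the decomposition of the joint effect attributes exactly
    ``ap_genetic`` / ``ap_lifestyle`` of the double-exposure excess to
    each exposure alone, the remainder to their additive interaction —
    the genetic-dominant pattern. ``rr11`` is the joint relative risk at
    the double-exposed corner; a positive product term requires a modest
    ``rr11`` (below ~2.3 for the default split).
    """
    import math

    from scipy import stats as _stats

    tail = float(_stats.norm.pdf(_stats.norm.ppf(0.8)) / 0.2)
    g0, g1, l0, l1 = -tail, tail, 0.5, 4.5
    dg, dl = g1 - g0, l1 - l0

    x = rr11 - 1.0
    rr10 = 1.0 + ap_genetic * x
    rr01 = 1.0 + ap_lifestyle * x
    b_int = (math.log(rr11) - math.log(rr10) - math.log(rr01)) / (dg * dl)
    b_pgs = (math.log(rr10) - b_int * dg * l0) / dg
    b_life = (math.log(rr01) - b_int * g0 * dl) / dl
    defaults = dict(beta_pgs=b_pgs, beta_lifestyle=b_life,
                    beta_interaction=b_int)
    defaults.update(overrides)
    return SimulationConfig(**defaults)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def _require_finite(value: float, name: str) -> None:
    import math

    if not math.isfinite(value):
        raise ValueError(f"{name} must be finite, got {value}")
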