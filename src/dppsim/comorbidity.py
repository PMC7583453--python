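"""Simplified annual comorbidity and mortality models.

The host physiology around the dementia adaptation: diabetes diagnosis when
HbA1c crosses the diagnostic threshold, a single log-linear cardiovascular
hazard (a configurable stand-in for a QRISK-style equation), age-dependent
incidence of other chronic conditions, and all-cause mortality from a
baseline lifetable multiplied by condition hazard ratios on the hazard scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigError, InputError
from .population import Individual


def hazard_to_probability(h):
    """p = 1 - exp(-h) for an annual hazard h >= 0."""
    h = np.asarray(h, dtype=float)
    if np.any(h < 0):
        raise InputError("hazard must be >= 0")
    return -np.expm1(-h)


def probability_to_hazard(p):
    """Inverse transform: h = -ln(1 - p)."""
    p = np.asarray(p, dtype=float)
    if np.any((p < 0) | (p >= 1)):
        raise InputError("probability must be in [0, 1)")
    return -np.log1p(-p)


class LifeTable:
    """Annual death probabilities q(age, sex) on integer ages.

    The shipped default is a synthetic Gompertz-Makeham table,
    q(age) = min(0.7, 0.0002 + exp(-10.5 + 0.087*age)), identical for both
    sexes with a configurable male hazard excess.  A national lifetable can
    be supplied as a CSV (age, q_male, q_female).
    """

    def __init__(self, ages: np.ndarray, q_male: np.ndarray, q_female: np.ndarray):
        self.ages = np.asarray(ages, dtype=int)
        if self.ages.size == 0 or np.any(np.diff(self.ages) != 1):
            raise ConfigError("lifetable ages must be consecutive integers")
        self.q_male = np.asarray(q_male, dtype=float)
        self.q_female = np.asarray(q_female, dtype=float)
        for q in (self.q_male, self.q_female):
            if q.shape != self.ages.shape or np.any((q < 0) | (q > 1)):
                raise ConfigError("lifetable q values must be in [0, 1]")

    @classmethod
    def synthetic_default(cls, male_excess: float = 1.3,
                          age_min: int = 0, age_max: int = 105) -> "LifeTable":
        ages = np.arange(age_min, age_max + 1)
        q = np.minimum(0.7, 0.0002 + np.exp(-10.5 + 0.087 * ages))
        h = -np.log1p(-q)
        q_male = np.minimum(0.7, -np.expm1(-h * male_excess))
        return cls(ages, q_male, q)

    @classmethod
    def from_csv(cls, path) -> "LifeTable":
        df = pd.read_csv(path)
        for c in ("age", "q_male", "q_female"):
            if c not in df.columns:
                raise ConfigError(f"lifetable CSV missing column '{c}'")
        df = df.sort_values("age")
        return cls(df["age"].to_numpy(), df["q_male"].to_numpy(),
                   df["q_female"].to_numpy())

    def q(self, age, is_male):
        """Baseline annual death probability; errors outside table coverage."""
        age_i = np.asarray(np.floor(age), dtype=int)
        if np.any(age_i < self.ages[0]) or np.any(age_i > self.ages[-1]):
            raise ConfigError("age outside lifetable coverage")
        idx = age_i - self.ages[0]
        return np.where(np.asarray(is_male, dtype=bool),
                        self.q_male[idx], self.q_female[idx])


@dataclass
class CVDHazardParams:
    """Log-linear annual cardiovascular event hazard (stand-in equation).

    Centred so a 57-year-old non-smoking woman at cohort-mean SBP without
    diabetes has ``baseline_hazard`` (default ~1%/year) risk.  Coefficients
    are calibration knobs, not epidemiological claims.
    """

    baseline_hazard: float = 0.01
    coef_age_per_decade: float = 0.55
    coef_sbp_per_10mmhg: float = 0.12
    coef_male: float = 0.30
    coef_current_smoker: float = 0.40
    coef_diabetes: float = 0.50
    coef_total_chol: float = 0.0
    coef_hdl_chol: float = 0.0
    ref_age: float = 57.0
    ref_sbp: float = 130.0
    ref_tc: float = 5.2
    ref_hdl: float = 1.5

    def hazard(self, age, sbp, is_male, is_current_smoker, has_diabetes,
               total_chol=None, hdl_chol=None):
        lp = (self.coef_age_per_decade * (np.asarray(age) - self.ref_age) / 10.0
              + self.coef_sbp_per_10mmhg * (np.asarray(sbp) - self.ref_sbp) / 10.0
              + self.coef_male * np.asarray(is_male, dtype=float)
              + self.coef_current_smoker * np.asarray(is_current_smoker, dtype=float)
              + self.coef_diabetes * np.asarray(has_diabetes, dtype=float))
        if total_chol is not None:
            lp = lp + self.coef_total_chol * (np.asarray(total_chol) - self.ref_tc)
        if hdl_chol is not None:
            lp = lp + self.coef_hdl_chol * (np.asarray(hdl_chol) - self.ref_hdl)
        return self.baseline_hazard * np.exp(lp)


@dataclass
class IncidenceRule:
    """Annual hazard h = base_rate * exp(log_age_slope * (age - age_ref))."""

    base_rate: float
    age_ref: float = 60.0
    log_age_slope: float = 0.0

    def hazard(self, age):
        return self.base_rate * np.exp(self.log_age_slope * (np.asarray(age) - self.age_ref))


def _default_other_conditions() -> dict[str, IncidenceRule]:
    return {
        "cancer": IncidenceRule(0.002, 60.0, 0.04),
        "osteoarthritis": IncidenceRule(0.005, 60.0, 0.02),
        "depression": IncidenceRule(0.004, 60.0, 0.0),
        "chf": IncidenceRule(0.0008, 60.0, 0.07),
    }


@dataclass
class ComorbidityParams:
    diabetes_hba1c_threshold: float = 6.5
    diabetes_detection_prob: float = 0.5
    cvd: CVDHazardParams = field(default_factory=CVDHazardParams)
    stroke_fraction: float = 0.25
    other_conditions: dict[str, IncidenceRule] = field(default_factory=_default_other_conditions)
    lifetable: LifeTable = field(default_factory=LifeTable.synthetic_default)
    # All-cause mortality hazard ratios of broadly UK-cohort magnitude:
    # established CVD ~2, cancer ~2, type 2 diabetes ~1.6.
    hr_mortality_cvd: float = 2.0
    hr_mortality_cancer: float = 2.0
    hr_mortality_diabetes: float = 1.6

    def validate(self) -> None:
        if not 0.0 <= self.diabetes_detection_prob <= 1.0:
            raise ConfigError("diabetes detection probability outside [0, 1]")
        if not 0.0 <= self.stroke_fraction <= 1.0:
            raise ConfigError("stroke_fraction outside [0, 1]")
        for name, hr in (("hr_mortality_cvd", self.hr_mortality_cvd),
                         ("hr_mortality_cancer", self.hr_mortality_cancer),
                         ("hr_mortality_diabetes", self.hr_mortality_diabetes)):
            if hr <= 0:
                raise ConfigError(f"{name} must be > 0")


def dementia_mortality_hr(age, dementia_diagnosed, hr_60_84: float, hr_85_plus: float):
    """Dementia hazard ratio on all-cause mortality: one HR for ages 60-84
    and a smaller one from age 85, reflecting attenuation at the oldest ages."""
    age = np.asarray(age, dtype=float)
    dem = np.asarray(dementia_diagnosed, dtype=bool)
    hr = np.where(age >= 85.0, hr_85_plus, np.where(age >= 60.0, hr_60_84, 1.0))
    return np.where(dem, hr, 1.0)


def death_probability(age, is_male, cvd_history, cancer, diabetes_diagnosed,
                      dementia_diagnosed, params: ComorbidityParams,
                      hr_dementia_60_84: float = 1.0, hr_dementia_85_plus: float = 1.0):
    """Baseline lifetable q -> hazard, multiplied by condition HRs, back to p."""
    q = params.lifetable.q(age, is_male)
    h = -np.log1p(-np.minimum(q, 1.0 - 1e-12))
    hr = np.ones_like(h)
    hr = hr * np.where(np.asarray(cvd_history, dtype=bool), params.hr_mortality_cvd, 1.0)
    hr = hr * np.where(np.asarray(cancer, dtype=bool), params.hr_mortality_cancer, 1.0)
    hr = hr * np.where(np.asarray(diabetes_diagnosed, dtype=bool), params.hr_mortality_diabetes, 1.0)
    hr = hr * dementia_mortality_hr(age, dementia_diagnosed,
                                    hr_dementia_60_84, hr_dementia_85_plus)
    return -np.expm1(-h * hr)


def annual_death_probability(i: Individual, params: ComorbidityParams,
                             dementia_hrs=None) -> float:
    """Per-individual wrapper around :func:`death_probability`."""
    if not i.alive:
        raise InputError("individual is not alive")
    hr1 = dementia_hrs.hr_60_84 if dementia_hrs is not None else 1.0
    hr2 = dementia_hrs.hr_85_plus if dementia_hrs is not None else 1.0
    return float(death_probability(
        i.age, i.sex == "male", i.cvd_history, i.cancer, i.diabetes_diagnosed,
        i.dementia_diagnosed, params, hr1, hr2))


def simulate_events(i: Individual, params: ComorbidityParams,
                    uniforms: dict[str, float]) -> Individual:
    """One annual cycle of event draws for a single individual (in place).

    ``uniforms`` holds one U(0,1) draw per event stream: diabetes, cvd,
    stroke, cancer, osteoarthritis, depression, chf.  Disease flags are
    absorbing.  The vectorised engine applies the same rules cohort-wide.
    """
    if not i.alive:
        raise InputError("individual is not alive")
    if (not i.diabetes_diagnosed
            and i.hba1c >= params.diabetes_hba1c_threshold
            and uniforms.get("diabetes", 1.0) < params.diabetes_detection_prob):
        i.diabetes_diagnosed = True
    h_cvd = params.cvd.hazard(i.age, i.sbp, i.sex == "male",
                              i.smoking == "current", i.diabetes_diagnosed,
                              i.total_chol, i.hdl_chol)
    if uniforms.get("cvd", 1.0) < hazard_to_probability(h_cvd):
        i.cvd_history = True
        if uniforms.get("stroke", 1.0) < params.stroke_fraction:
            i.stroke_history = True
    for name, rule in params.other_conditions.items():
        if not getattr(i, name) and uniforms.get(name, 1.0) < hazard_to_probability(rule.hazard(i.age)):
            setattr(i, name, True)
    return i
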