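"""Annual metabolic risk-factor trajectories and intervention effects.

Each factor (BMI, SBP, total and HDL cholesterol, HbA1c) drifts annually by a
simple configurable rule (intercept + optional age slope + optional shift
from age 60) plus Gaussian residual noise, clamped to a physiological range.
The diabetes-prevention intervention shifts factors by its full effect in
year 1 and tapers linearly back to the counterfactual level over the duration
of effect (default 5 years), after which the two arms coincide exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigError

FACTORS = ("bmi", "sbp", "total_chol", "hdl_chol", "hba1c")

#: Clamp ranges applied after every annual update.
FACTOR_BOUNDS = {
    "bmi": (13.0, 70.0),
    "sbp": (70.0, 250.0),
    "total_chol": (1.5, 15.0),
    "hdl_chol": (0.3, 5.0),
    "hba1c": (4.0, 20.0),
}


@dataclass
class DriftRule:
    """Annual drift: intercept + age_slope*age + post60_shift*[age >= 60]."""

    intercept: float = 0.0
    age_slope: float = 0.0
    post60_shift: float = 0.0

    def drift(self, age):
        age = np.asarray(age, dtype=float)
        return self.intercept + self.age_slope * age + self.post60_shift * (age >= 60.0)


def _default_drift() -> dict[str, DriftRule]:
    # Stand-in annual drifts: modest adiposity gain reversing after 60,
    # rising blood pressure and glycaemia, cholesterol decline in older age.
    return {
        "bmi": DriftRule(intercept=0.05, post60_shift=-0.10),
        "sbp": DriftRule(intercept=0.5),
        "total_chol": DriftRule(intercept=0.01, post60_shift=-0.03),
        "hdl_chol": DriftRule(),
        "hba1c": DriftRule(intercept=0.02),
    }


def _default_residual_sd() -> dict[str, float]:
    # HbA1c SD reflects realistic within-person year-to-year variability
    # (~0.1 percentage points) in the impaired-glucose-regulation range.
    return {"bmi": 0.3, "sbp": 3.0, "total_chol": 0.15, "hdl_chol": 0.05,
            "hba1c": 0.10}


@dataclass
class TrajectoryParams:
    drift: dict[str, DriftRule] = field(default_factory=_default_drift)
    residual_sd: dict[str, float] = field(default_factory=_default_residual_sd)

    def validate(self) -> None:
        for f in FACTORS:
            if f not in self.drift:
                raise ConfigError(f"missing drift rule for factor '{f}'")
            if f not in self.residual_sd:
                raise ConfigError(f"missing residual SD for factor '{f}'")
            if self.residual_sd[f] < 0:
                raise ConfigError(f"residual SD for '{f}' must be >= 0")


@dataclass
class InterventionEffect:
    """First-year metabolic effects of the programme and their decay.

    Defaults are the pooled effectiveness estimates used for the NHS DPP:
    BMI -1.47 kg/m^2, HbA1c -0.20%, SBP -6.57 mm Hg, total cholesterol
    -0.28 mmol/L, at a per-participant cost of GBP 270, with a 5-year
    duration of effect.
    """

    delta_bmi: float = -1.47
    delta_hba1c: float = -0.20
    delta_sbp: float = -6.57
    delta_tc: float = -0.28
    se_bmi: float = 0.156
    se_hba1c: float = 0.043
    se_sbp: float = 0.923
    se_tc: float = 0.028
    cost: float = 270.0
    duration: float = 5.0

    def validate(self) -> None:
        if self.duration <= 0:
            raise ConfigError("intervention duration must be > 0")
        if self.cost < 0:
            raise ConfigError("intervention cost must be >= 0")

    @property
    def deltas(self) -> dict[str, float]:
        return {"bmi": self.delta_bmi, "sbp": self.delta_sbp,
                "total_chol": self.delta_tc, "hdl_chol": 0.0,
                "hba1c": self.delta_hba1c}


def project_factor(current_value, age, factor: str, params: TrajectoryParams,
                   noise):
    """One annual step: current + drift(age) + residual_sd * noise, clamped.

    Works elementwise on arrays; ``noise`` is a standard-normal draw.
    """
    if factor not in FACTOR_BOUNDS:
        raise ConfigError(f"unknown factor '{factor}'")
    rule = params.drift[factor]
    sd = params.residual_sd[factor]
    lo, hi = FACTOR_BOUNDS[factor]
    nxt = np.asarray(current_value, dtype=float) + rule.drift(age) + sd * np.asarray(noise)
    return np.clip(nxt, lo, hi)


def intervention_offset(effect_delta, year_since_start, duration):
    """Taper of the intervention effect.

    Full delta in year 1, linear attenuation thereafter, zero from year
    duration+1 onward: ``delta * max(0, (duration + 1 - y) / duration)``.
    """
    y = np.asarray(year_since_start, dtype=float)
    frac = np.maximum(0.0, (duration + 1.0 - y) / duration)
    frac = np.minimum(frac, 1.0)
    return np.asarray(effect_delta, dtype=float) * frac
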