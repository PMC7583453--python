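"""Costs, utilities, discounting and net monetary benefit.

Costing takes the NHS + personal social services perspective in 2016-2017
GBP.  Costs accumulate additively across conditions; health-related quality
of life decrements are applied multiplicatively to the individual's
age-adjusted baseline EQ-5D to avoid double counting under multimorbidity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dementia import severity_band
from .errors import ConfigError
from .population import Individual

DEMENTIA_BANDS = ("mild", "moderate", "severe")


def _default_dementia_health_costs() -> dict[str, float]:
    return {"mild": 3103.0, "moderate": 8293.0, "severe": 9841.0}


def _default_dementia_social_costs() -> dict[str, float]:
    return {"mild": 5674.0, "moderate": 22703.0, "severe": 23466.0}


def _default_condition_costs() -> dict[str, float]:
    # Annual health-care costs per prevalent condition; configurable
    # stand-ins of plausible magnitude for the non-dementia sub-models.
    return {
        "cvd_event_year": 5000.0,
        "cvd_history_year": 800.0,
        "diabetes": 1800.0,
        "cancer": 5000.0,
        "osteoarthritis": 800.0,
        "depression": 500.0,
        "chf": 2000.0,
    }


@dataclass
class CostParams:
    """Annual costs (GBP, 2016-2017) by dementia severity band and condition.

    Dementia health-care costs: mild 3103, moderate 8293, severe 9841;
    social-care costs: mild 5674, moderate 22703, severe 23466 (uncertainty
    assumed 10% of the mean).  The one-off dementia diagnosis cost defaults
    to zero (configuration hook).
    """

    dementia_health: dict[str, float] = field(default_factory=_default_dementia_health_costs)
    dementia_social: dict[str, float] = field(default_factory=_default_dementia_social_costs)
    dementia_cost_se_frac: float = 0.10
    dementia_diagnosis_cost: float = 0.0
    condition_costs: dict[str, float] = field(default_factory=_default_condition_costs)
    currency_year: str = "2016-2017 GBP"

    def validate(self) -> None:
        for comp in (self.dementia_health, self.dementia_social):
            for band in DEMENTIA_BANDS:
                if band not in comp or comp[band] < 0:
                    raise ConfigError(f"missing/negative dementia cost for '{band}'")
            if not comp["mild"] <= comp["moderate"] <= comp["severe"]:
                raise ConfigError("dementia costs must be monotone mild <= moderate <= severe")
        if any(c < 0 for c in self.condition_costs.values()):
            raise ConfigError("condition costs must be >= 0")
        if self.dementia_diagnosis_cost < 0:
            raise ConfigError("dementia diagnosis cost must be >= 0")


def _default_mmse_multipliers() -> dict[str, float]:
    return {"21-25": 0.93, "15-20": 0.725, "10-14": 0.710, "0-9": 0.478}


def _default_condition_multipliers() -> dict[str, float]:
    # Multiplicative HRQoL decrements for non-dementia conditions
    # (configurable stand-ins in (0, 1]).
    return {
        "cvd_history": 0.90,
        "cancer": 0.85,
        "osteoarthritis": 0.90,
        "depression": 0.85,
        "chf": 0.85,
    }


@dataclass
class UtilityParams:
    """Multiplicative utility decrements and the age-decline rule.

    Cognitive-impairment multipliers by MMSE band: 21-25 -> 0.93,
    15-20 -> 0.725, 10-14 -> 0.710, 0-9 -> 0.478 (no decrement from 26).
    """

    mmse_multipliers: dict[str, float] = field(default_factory=_default_mmse_multipliers)
    condition_multipliers: dict[str, float] = field(default_factory=_default_condition_multipliers)
    utility_se_frac: float = 0.10
    age_quadratic_coef: float = 0.0002
    age_multiplier_floor: float = 0.4

    def validate(self) -> None:
        for m in list(self.mmse_multipliers.values()) + list(self.condition_multipliers.values()):
            if not 0.0 < m <= 1.0:
                raise ConfigError("utility multipliers must be in (0, 1]")

    def age_multiplier(self, age):
        """1 - c*(age - 40)+^2, floored; applied to baseline EQ-5D."""
        a = np.maximum(0.0, np.asarray(age, dtype=float) - 40.0)
        return np.maximum(self.age_multiplier_floor, 1.0 - self.age_quadratic_coef * a ** 2)

    def mmse_multiplier_value(self, utility_band: str) -> float:
        if utility_band == "none":
            return 1.0
        return self.mmse_multipliers[utility_band]


@dataclass
class EconomicsParams:
    discount_rate: float = 0.035
    willingness_to_pay: float = 20000.0

    def validate(self) -> None:
        if self.discount_rate < 0:
            raise ConfigError("discount rate must be >= 0")
        if self.willingness_to_pay < 0:
            raise ConfigError("willingness to pay must be >= 0")


def annual_utility(i: Individual, params: UtilityParams) -> float:
    """Utility accrued this cycle: baseline EQ-5D x age multiplier x
    condition multipliers x MMSE-band multiplier."""
    u = i.baseline_eq5d * float(params.age_multiplier(i.age))
    flags = {
        "cvd_history": i.cvd_history,
        "cancer": i.cancer,
        "osteoarthritis": i.osteoarthritis,
        "depression": i.depression,
        "chf": i.chf,
    }
    for name, active in flags.items():
        if active:
            u *= params.condition_multipliers.get(name, 1.0)
    if i.dementia_diagnosed and i.mmse is not None:
        _, ub = severity_band(i.mmse)
        u *= params.mmse_multiplier_value(ub)
    return u


def annual_costs(i: Individual, params: CostParams, arm: str, year: int,
                 cvd_event_this_year: bool = False,
                 new_dementia_diagnosis: bool = False,
                 intervention_cost: float = 270.0) -> dict[str, float]:
    """Undiscounted cost components for one cycle, keyed to mirror the
    reporting layout: health, social, dementia, cardiovascular, intervention.

    The dementia component (health + social band costs) also contributes to
    the health/social totals per its split; the intervention cost is charged
    once, in year 1, in the intervention arm, and sits inside health care.
    """
    cc = params.condition_costs
    cardiovascular = 0.0
    if cvd_event_this_year:
        cardiovascular += cc.get("cvd_event_year", 0.0)
    elif i.cvd_history:
        cardiovascular += cc.get("cvd_history_year", 0.0)
    other_health = 0.0
    for cond in ("diabetes", "cancer", "osteoarthritis", "depression", "chf"):
        flag = i.diabetes_diagnosed if cond == "diabetes" else getattr(i, cond)
        if flag:
            other_health += cc.get(cond, 0.0)
    dem_health = dem_social = 0.0
    if i.dementia_diagnosed and i.mmse is not None:
        band, _ = severity_band(i.mmse)
        if band != "none":
            dem_health = params.dementia_health[band]
            dem_social = params.dementia_social[band]
        if new_dementia_diagnosis:
            dem_health += params.dementia_diagnosis_cost
    interv = intervention_cost if (arm == "dpp" and year == 1) else 0.0
    health = cardiovascular + other_health + dem_health + interv
    social = dem_social
    return {
        "health": health,
        "social": social,
        "total": health + social,
        "dementia": dem_health + dem_social,
        "cardiovascular": cardiovascular,
        "intervention": interv,
    }


def discount(value, t, r: float):
    """Discount ``value`` accrued in cycle ``t`` (cycle 0 undiscounted)."""
    if r < 0:
        raise ConfigError("discount rate must be >= 0")
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ConfigError("cycle index must be >= 0")
    out = np.asarray(value, dtype=float) / (1.0 + r) ** t
    return out if out.shape else float(out)


def incremental_net_benefit(delta_qaly: float, delta_cost: float,
                            willingness_to_pay: float) -> float:
    """Net monetary benefit of the increment: lambda * dQALY - dCost."""
    return willingness_to_pay * delta_qaly - delta_cost
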