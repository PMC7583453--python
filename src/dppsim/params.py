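"""The full model parameter set: defaults, YAML configuration, PSA draws.

``ParameterSet.default()`` ships every published value as the default; any
field can be overridden from a nested YAML/JSON-style mapping whose top-level
blocks mirror the module layout (``population:``, ``trajectories:``,
``intervention:``, ``comorbidity:``, ``dementia:``, ``economics:``).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field

import numpy as np
import yaml

from .comorbidity import ComorbidityParams
from .dementia import (DementiaIncidenceParams, DementiaRiskReductionParams,
                       MMSEOnsetParams, MMSEProgressionParams, MortalityHRs)
from .economics import CostParams, EconomicsParams, UtilityParams
from .errors import ConfigError
from .population import PopulationParams
from .trajectories import InterventionEffect, TrajectoryParams


@dataclass
class ParameterSet:
    population: PopulationParams = field(default_factory=PopulationParams)
    trajectories: TrajectoryParams = field(default_factory=TrajectoryParams)
    intervention: InterventionEffect = field(default_factory=InterventionEffect)
    comorbidity: ComorbidityParams = field(default_factory=ComorbidityParams)
    dementia_incidence: DementiaIncidenceParams = field(default_factory=DementiaIncidenceParams)
    caide: DementiaRiskReductionParams = field(default_factory=DementiaRiskReductionParams)
    mmse_onset: MMSEOnsetParams = field(default_factory=MMSEOnsetParams)
    mmse_progression: MMSEProgressionParams = field(default_factory=MMSEProgressionParams)
    dementia_mortality: MortalityHRs = field(default_factory=MortalityHRs)
    costs: CostParams = field(default_factory=CostParams)
    utilities: UtilityParams = field(default_factory=UtilityParams)
    economics: EconomicsParams = field(default_factory=EconomicsParams)
    #: "frozen": the CAIDE risk ratio is fixed at its year-1 (full-effect)
    #: value and applied for the whole risk-reduction horizon; "recompute":
    #: re-evaluated each cycle on taper-adjusted factor values.
    caide_mode: str = "frozen"
    #: Whether utilities/costs accrue in the cycle in which death occurs.
    accrue_death_year: bool = False

    @classmethod
    def default(cls) -> "ParameterSet":
        return cls()

    def validate(self) -> None:
        if self.caide_mode not in ("frozen", "recompute"):
            raise ConfigError(f"unknown caide_mode '{self.caide_mode}'")
        self.population.validate()
        self.trajectories.validate()
        self.intervention.validate()
        self.comorbidity.validate()
        self.dementia_incidence.validate()
        self.caide.validate()
        self.mmse_onset.validate()
        self.mmse_progression.validate()
        self.dementia_mortality.validate()
        self.costs.validate()
        self.utilities.validate()
        self.economics.validate()

    # -- configuration ----------------------------------------------------

    _BLOCKS = {
        "population": "population",
        "trajectories": "trajectories",
        "intervention": "intervention",
        "comorbidity": "comorbidity",
        "dementia_incidence": "dementia_incidence",
        "caide": "caide",
        "mmse_onset": "mmse_onset",
        "mmse_progression": "mmse_progression",
        "dementia_mortality": "dementia_mortality",
        "costs": "costs",
        "utilities": "utilities",
        "economics": "economics",
    }

    @classmethod
    def from_dict(cls, cfg: dict) -> "ParameterSet":
        ps = cls.default()
        cfg = dict(cfg or {})
        # `dementia:` is accepted as an umbrella block with sub-blocks.
        dem = cfg.pop("dementia", None)
        if dem:
            for sub, target in (("incidence", "dementia_incidence"),
                                ("caide", "caide"),
                                ("mmse_onset", "mmse_onset"),
                                ("mmse_progression", "mmse_progression"),
                                ("mortality", "dementia_mortality")):
                if sub in dem:
                    cfg.setdefault(target, dem[sub])
            if "caide_mode" in dem:
                cfg.setdefault("caide_mode", dem["caide_mode"])
        for key, value in cfg.items():
            if key in ("caide_mode", "accrue_death_year"):
                setattr(ps, key, value)
                continue
            if key not in cls._BLOCKS:
                raise ConfigError(f"unknown configuration block '{key}'")
            obj = getattr(ps, key)
            _apply_overrides(obj, value)
        ps.validate()
        return ps

    @classmethod
    def from_yaml(cls, path) -> "ParameterSet":
        with open(path) as fh:
            cfg = yaml.safe_load(fh) or {}
        return cls.from_dict(cfg)

    def digest(self) -> str:
        """Stable hash of the parameter set, for provenance logging."""

        def enc(o):
            if dataclasses.is_dataclass(o) and not isinstance(o, type):
                return {f.name: enc(getattr(o, f.name)) for f in dataclasses.fields(o)}
            if isinstance(o, np.ndarray):
                return o.tolist()
            if isinstance(o, dict):
                return {str(k): enc(v) for k, v in o.items()}
            if isinstance(o, (list, tuple)):
                return [enc(v) for v in o]
            if hasattr(o, "ages"):  # lifetable
                return {"ages": o.ages.tolist(), "q_male": o.q_male.tolist(),
                        "q_female": o.q_female.tolist()}
            return o
        payload = json.dumps(enc(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _apply_overrides(obj, overrides: dict) -> None:
    if not isinstance(overrides, dict):
        raise ConfigError(f"configuration block must be a mapping, got {overrides!r}")
    for name, value in overrides.items():
        if not hasattr(obj, name):
            raise ConfigError(f"{type(obj).__name__} has no parameter '{name}'")
        current = getattr(obj, name)
        if dataclasses.is_dataclass(current) and isinstance(value, dict):
            _apply_overrides(current, value)
        elif isinstance(current, dict) and isinstance(value, dict) and current \
                and dataclasses.is_dataclass(next(iter(current.values()))):
            # e.g. drift rules / incidence rules keyed by name
            for k, v in value.items():
                if k in current and isinstance(v, dict):
                    _apply_overrides(current[k], v)
                else:
                    raise ConfigError(f"cannot override '{name}.{k}'")
        elif isinstance(current, dict) and isinstance(value, dict):
            current.update(value)
        elif isinstance(current, np.ndarray):
            setattr(obj, name, np.asarray(value, dtype=float))
        else:
            setattr(obj, name, value)


# -- probabilistic sensitivity analysis ----------------------------------

def _normal(rng, mean, se):
    return mean if se == 0 else float(rng.normal(mean, se))


def _lognormal(rng, mean, se):
    """Lognormal preserving the printed point estimate and SE scale
    (sigma = se/mean, the delta-method log-scale SD)."""
    if se == 0 or mean <= 0:
        return mean
    sigma = se / mean
    return float(mean * np.exp(rng.normal(0.0, sigma) - 0.5 * sigma ** 2))


def _gamma(rng, mean, se_frac):
    if se_frac == 0 or mean == 0:
        return mean
    shape = 1.0 / se_frac ** 2
    return float(rng.gamma(shape, mean / shape))


def _beta_scaled(rng, mean, se_frac):
    """Beta draw matched to mean and SD = se_frac * mean, kept in (0, 1]."""
    if se_frac == 0:
        return mean
    var = (se_frac * mean) ** 2
    if var >= mean * (1.0 - mean) or mean >= 1.0:
        return mean
    nu = mean * (1.0 - mean) / var - 1.0
    a, b = mean * nu, (1.0 - mean) * nu
    return float(np.clip(rng.beta(a, b), 1e-6, 1.0))


def draw_psa_sample(params: ParameterSet, rng: np.random.Generator) -> ParameterSet:
    """One PSA draw: a deep copy of ``params`` with uncertain parameters
    resampled from their distributions.

    Metabolic intervention effects: normal with their reported SEs.
    Hazard/odds ratios (dementia incidence, CAIDE, dementia mortality):
    lognormal with SEs on the printed scale.  MMSE progression
    coefficients: normal.  Dementia costs: gamma at 10% SE.  Utility
    multipliers: beta-scaled at 10% SE.  Draws are independent.
    """
    import copy

    p = copy.deepcopy(params)
    iv = p.intervention
    iv.delta_bmi = _normal(rng, iv.delta_bmi, iv.se_bmi)
    iv.delta_hba1c = _normal(rng, iv.delta_hba1c, iv.se_hba1c)
    iv.delta_sbp = _normal(rng, iv.delta_sbp, iv.se_sbp)
    iv.delta_tc = _normal(rng, iv.delta_tc, iv.se_tc)

    di = p.dementia_incidence
    di.hr_bmi_per_unit = _lognormal(rng, di.hr_bmi_per_unit, di.se_hr_bmi)
    di.hr_bmi_sq_per_unit = _lognormal(rng, di.hr_bmi_sq_per_unit, di.se_hr_bmi_sq)
    di.hr_antihypertensives = _lognormal(rng, di.hr_antihypertensives,
                                         di.se_hr_antihypertensives)
    di.hr_stroke = _lognormal(rng, di.hr_stroke, di.se_hr_stroke)
    di.hr_diabetes = _lognormal(rng, di.hr_diabetes, di.se_hr_diabetes)

    ca = p.caide
    ca.or_obese = _lognormal(rng, ca.or_obese, ca.se_or_obese)
    ca.or_hypertension = _lognormal(rng, ca.or_hypertension, ca.se_or_hypertension)
    ca.or_hyperlipidemia = _lognormal(rng, ca.or_hyperlipidemia, ca.se_or_hyperlipidemia)

    mp = p.mmse_progression
    mp.intercept = _normal(rng, mp.intercept, mp.se_intercept)
    mp.b_pm1 = _normal(rng, mp.b_pm1, mp.se_pm1)
    mp.b_pm2 = _normal(rng, mp.b_pm2, mp.se_pm2)
    mp.b_pm3 = _normal(rng, mp.b_pm3, mp.se_pm3)
    mp.b_age = _normal(rng, mp.b_age, mp.se_age)
    mp.b_prev_rate = _normal(rng, mp.b_prev_rate, mp.se_prev_rate)

    dm = p.dementia_mortality
    dm.hr_60_84 = _lognormal(rng, dm.hr_60_84, dm.se_60_84)
    dm.hr_85_plus = _lognormal(rng, dm.hr_85_plus, dm.se_85_plus)

    for band in ("mild", "moderate", "severe"):
        p.costs.dementia_health[band] = _gamma(
            rng, p.costs.dementia_health[band], p.costs.dementia_cost_se_frac)
        p.costs.dementia_social[band] = _gamma(
            rng, p.costs.dementia_social[band], p.costs.dementia_cost_se_frac)
    # Keep severity monotonicity after independent draws (sorted within component).
    for comp in (p.costs.dementia_health, p.costs.dementia_social):
        vals = sorted(comp[b] for b in ("mild", "moderate", "severe"))
        comp["mild"], comp["moderate"], comp["severe"] = vals

    for band, m in list(p.utilities.mmse_multipliers.items()):
        p.utilities.mmse_multipliers[band] = _beta_scaled(
            rng, m, p.utilities.utility_se_frac)
    return p
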