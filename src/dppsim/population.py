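"""Synthetic cohort generation for the NHS DPP-eligible population.

Generates individuals statistically emulating the Health Survey for England
2014 subset eligible for the NHS diabetes prevention programme: HbA1c in the
impaired-glucose-regulation window 6.0-6.4%, age >= 16, no prevalent diabetes
diagnosis.  Continuous risk factors are drawn from a Gaussian copula so that
marginal means/SDs match the published summary statistics while adiposity,
blood pressure and glycaemia remain positively correlated.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import ndtr
from scipy.stats import truncnorm

from .errors import ConfigError, InputError

# Order of the continuous factors in the copula correlation matrix.
CONTINUOUS_FACTORS = ("age", "bmi", "sbp", "total_chol", "hdl_chol", "hba1c")

HBA1C_ELIGIBLE_LOW = 6.0
HBA1C_ELIGIBLE_HIGH = 6.4
AGE_ELIGIBLE_MIN = 16.0

#: Wide physiological clamp ranges used when sampling (and when projecting
#: trajectories; see :mod:`dppsim.trajectories`).
SAMPLING_BOUNDS = {
    "bmi": (13.0, 70.0),
    "sbp": (70.0, 250.0),
    "total_chol": (1.5, 15.0),
    "hdl_chol": (0.3, 5.0),
}


def _default_correlation() -> np.ndarray:
    """Plausible joint structure: BMI-SBP 0.2, BMI-HbA1c 0.15, SBP-age 0.3."""
    r = np.eye(len(CONTINUOUS_FACTORS))
    idx = {f: i for i, f in enumerate(CONTINUOUS_FACTORS)}
    pairs = [("bmi", "sbp", 0.20), ("bmi", "hba1c", 0.15), ("sbp", "age", 0.30)]
    for a, b, rho in pairs:
        r[idx[a], idx[b]] = r[idx[b], idx[a]] = rho
    return r


@dataclass
class PopulationParams:
    """Marginal distributions and joint structure of the eligible cohort.

    Defaults reproduce the published baseline characteristics of the
    HSE 2014 NHS-DPP-eligible population (n = 2331): 44.7% male, mean age
    57.1 (SD 17.6), mean BMI 28.5 kg/m^2 (SD 5.4), mean SBP 129.9 mm Hg,
    mean HbA1c 6.2% truncated to the eligibility window.
    """

    prop_male: float = 0.447
    prop_nonwhite: float = 0.107
    prop_current_smoker: float = 0.191
    prop_past_smoker: float = 0.294
    prop_hypertension: float = 0.264
    prop_anxiety: float = 0.10
    prop_nsaid: float = 0.15

    age_mean: float = 57.1
    age_sd: float = 17.6
    age_min: float = 16.0
    age_max: float = 90.0
    bmi_mean: float = 28.5
    bmi_sd: float = 5.4
    sbp_mean: float = 129.9
    sbp_sd: float = 17.7
    tc_mean: float = 5.2
    tc_sd: float = 1.1
    hdl_mean: float = 1.5
    hdl_sd: float = 0.47
    hba1c_mean: float = 6.2
    hba1c_sd: float = 0.15

    correlation: np.ndarray = field(default_factory=_default_correlation)

    # Baseline EQ-5D rule: intercept - slope*(age-40)+ with individual noise.
    eq5d_intercept: float = 0.95
    eq5d_age_slope: float = 0.003
    eq5d_noise_sd: float = 0.10

    def validate(self) -> None:
        props = {
            "prop_male": self.prop_male,
            "prop_nonwhite": self.prop_nonwhite,
            "prop_current_smoker": self.prop_current_smoker,
            "prop_past_smoker": self.prop_past_smoker,
            "prop_hypertension": self.prop_hypertension,
            "prop_anxiety": self.prop_anxiety,
            "prop_nsaid": self.prop_nsaid,
        }
        for name, p in props.items():
            if not 0.0 <= p <= 1.0:
                raise ConfigError(f"{name}={p} outside [0, 1]")
        if self.prop_current_smoker + self.prop_past_smoker > 1.0:
            raise ConfigError("smoking proportions sum to more than 1")
        for name in ("age_sd", "bmi_sd", "sbp_sd", "tc_sd", "hdl_sd", "hba1c_sd"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be > 0")
        r = np.asarray(self.correlation, dtype=float)
        k = len(CONTINUOUS_FACTORS)
        if r.shape != (k, k):
            raise ConfigError(f"correlation matrix must be {k}x{k}")
        if not np.allclose(r, r.T):
            raise ConfigError("correlation matrix must be symmetric")
        if not np.allclose(np.diag(r), 1.0):
            raise ConfigError("correlation matrix must have unit diagonal")
        if np.linalg.eigvalsh(r).min() < -1e-8:
            raise ConfigError("correlation matrix is not positive semi-definite")


@dataclass
class Individual:
    """One simulated person: fixed attributes, risk factors and disease state.

    ``mmse`` is defined only after a dementia diagnosis; ``prev_mmse_rate``
    is the previous year's rate of MMSE change (score/year), used by the
    cognitive-decline regression.
    """

    id: int
    age: float
    sex: str  # "male" | "female"
    ethnicity: str  # "white" | "nonwhite"
    smoking: str  # "never" | "past" | "current"
    on_antihypertensives: bool
    ses_band: int  # ordinal 1-5
    bmi: float
    sbp: float
    total_chol: float
    hdl_chol: float
    hba1c: float
    baseline_eq5d: float
    anxiety: bool = False
    nsaid_use: bool = False
    diabetes_diagnosed: bool = False
    cvd_history: bool = False
    stroke_history: bool = False
    chf: bool = False
    cancer: bool = False
    osteoarthritis: bool = False
    depression: bool = False
    dementia_diagnosed: bool = False
    alive: bool = True
    mmse: float | None = None
    prev_mmse_rate: float = 0.0
    # Per-person ledgers, filled in by the simulation engine on request.
    costs_discounted: dict = field(default_factory=dict)
    qalys_discounted: float = 0.0


COHORT_COLUMNS = [
    "id", "age", "sex", "ethnicity", "smoking", "on_antihypertensives",
    "ses_band", "anxiety", "nsaid_use", "bmi", "sbp", "total_chol",
    "hdl_chol", "hba1c", "baseline_eq5d", "diabetes_diagnosed",
]

_OPTIONAL_DEFAULTS = {
    "ethnicity": "white",
    "smoking": "never",
    "on_antihypertensives": False,
    "ses_band": 3,
    "anxiety": False,
    "nsaid_use": False,
    "baseline_eq5d": None,  # filled from the age rule if absent
    "diabetes_diagnosed": False,
}


def is_eligible(i: Individual) -> bool:
    """NHS DPP eligibility: age >= 16, HbA1c in [6.0, 6.4], no diabetes."""
    if i.hba1c is None or not np.isfinite(i.hba1c):
        raise InputError(f"individual {i.id}: HbA1c undefined")
    return (
        i.age >= AGE_ELIGIBLE_MIN
        and HBA1C_ELIGIBLE_LOW <= i.hba1c <= HBA1C_ELIGIBLE_HIGH
        and not i.diabetes_diagnosed
    )


def baseline_eq5d_rule(age, params: PopulationParams, noise=0.0):
    """Age-declining baseline utility, clamped to [0, 1]."""
    base = params.eq5d_intercept - params.eq5d_age_slope * np.maximum(0.0, np.asarray(age) - 40.0)
    return np.clip(base + noise, 0.0, 1.0)


def sample_cohort(params: PopulationParams, seed: int, n: int | None = None) -> list[Individual]:
    """Draw ``n`` eligible individuals from the Gaussian-copula population model.

    Age and HbA1c use truncated-normal marginals (age to [age_min, age_max],
    HbA1c to the eligibility window); the other continuous factors are normal,
    clipped to wide physiological ranges.  Reproducible for a fixed seed.
    """
    params.validate()
    if n is None:
        raise InputError("cohort size n must be given")
    if n < 0:
        raise InputError(f"cohort size must be >= 0, got {n}")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    if n == 0:
        return []

    r = np.asarray(params.correlation, dtype=float)
    # PSD factor robust to semi-definite matrices.
    w, v = np.linalg.eigh(r)
    l = v * np.sqrt(np.clip(w, 0.0, None))
    z = rng.standard_normal((n, len(CONTINUOUS_FACTORS))) @ l.T
    u = ndtr(z)
    u = np.clip(u, 1e-12, 1.0 - 1e-12)
    col = {f: i for i, f in enumerate(CONTINUOUS_FACTORS)}

    def trunc_ppf(uu, mean, sd, lo, hi):
        a, b = (lo - mean) / sd, (hi - mean) / sd
        return truncnorm.ppf(uu, a, b, loc=mean, scale=sd)

    age = trunc_ppf(u[:, col["age"]], params.age_mean, params.age_sd,
                    params.age_min, params.age_max)
    hba1c = trunc_ppf(u[:, col["hba1c"]], params.hba1c_mean, params.hba1c_sd,
                      HBA1C_ELIGIBLE_LOW, HBA1C_ELIGIBLE_HIGH)
    cont = {}
    for f, mean, sd in (("bmi", params.bmi_mean, params.bmi_sd),
                        ("sbp", params.sbp_mean, params.sbp_sd),
                        ("total_chol", params.tc_mean, params.tc_sd),
                        ("hdl_chol", params.hdl_mean, params.hdl_sd)):
        lo, hi = SAMPLING_BOUNDS[f]
        cont[f] = np.clip(mean + sd * z[:, col[f]], lo, hi)

    male = rng.random(n) < params.prop_male
    nonwhite = rng.random(n) < params.prop_nonwhite
    u_smoke = rng.random(n)
    smoking = np.where(
        u_smoke < params.prop_current_smoker, "current",
        np.where(u_smoke < params.prop_current_smoker + params.prop_past_smoker,
                 "past", "never"),
    )
    hypertension = rng.random(n) < params.prop_hypertension
    anxiety = rng.random(n) < params.prop_anxiety
    nsaid = rng.random(n) < params.prop_nsaid
    ses = rng.integers(1, 6, size=n)
    eq5d_noise = rng.normal(0.0, params.eq5d_noise_sd, size=n)
    eq5d = baseline_eq5d_rule(age, params, noise=eq5d_noise)

    cohort = [
        Individual(
            id=i,
            age=float(age[i]),
            sex="male" if male[i] else "female",
            ethnicity="nonwhite" if nonwhite[i] else "white",
            smoking=str(smoking[i]),
            on_antihypertensives=bool(hypertension[i]),
            ses_band=int(ses[i]),
            anxiety=bool(anxiety[i]),
            nsaid_use=bool(nsaid[i]),
            bmi=float(cont["bmi"][i]),
            sbp=float(cont["sbp"][i]),
            total_chol=float(cont["total_chol"][i]),
            hdl_chol=float(cont["hdl_chol"][i]),
            hba1c=float(hba1c[i]),
            baseline_eq5d=float(eq5d[i]),
        )
        for i in range(n)
    ]
    return cohort


def cohort_to_frame(cohort: Sequence[Individual]) -> pd.DataFrame:
    rows = [{c: getattr(i, c) for c in COHORT_COLUMNS} for i in cohort]
    return pd.DataFrame(rows, columns=COHORT_COLUMNS)


def write_cohort_csv(cohort: Sequence[Individual], path) -> None:
    cohort_to_frame(cohort).to_csv(path, index=False)


def read_cohort_csv(path, params: PopulationParams | None = None) -> list[Individual]:
    """Read a cohort CSV; missing optional columns are filled from defaults.

    Required columns: age, sex, bmi, sbp, total_chol, hdl_chol, hba1c.
    A missing ``baseline_eq5d`` is filled from the age rule (no noise).
    """
    params = params or PopulationParams()
    df = pd.read_csv(path)
    required = ["age", "sex", "bmi", "sbp", "total_chol", "hdl_chol", "hba1c"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise InputError(f"cohort CSV missing required columns: {missing}")
    if "id" not in df.columns:
        df["id"] = np.arange(len(df))
    for colname, default in _OPTIONAL_DEFAULTS.items():
        if colname not in df.columns:
            if colname == "baseline_eq5d":
                df[colname] = baseline_eq5d_rule(df["age"].to_numpy(), params)
            else:
                df[colname] = default
    out = []
    for _, row in df.iterrows():
        out.append(Individual(
            id=int(row["id"]),
            age=float(row["age"]),
            sex=str(row["sex"]),
            ethnicity=str(row["ethnicity"]),
            smoking=str(row["smoking"]),
            on_antihypertensives=bool(row["on_antihypertensives"]),
            ses_band=int(row["ses_band"]),
            anxiety=bool(row["anxiety"]),
            nsaid_use=bool(row["nsaid_use"]),
            bmi=float(row["bmi"]),
            sbp=float(row["sbp"]),
            total_chol=float(row["total_chol"]),
            hdl_chol=float(row["hdl_chol"]),
            hba1c=float(row["hba1c"]),
            baseline_eq5d=float(row["baseline_eq5d"]),
            diabetes_diagnosed=bool(row["diabetes_diagnosed"]),
        ))
    return out
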