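"""Dementia natural history: diagnosis incidence, direct risk reduction,
cognition at onset, MMSE progression, and severity banding.

Incidence from age 60 follows a primary-care (THIN-style) risk score: a
baseline diagnosis hazard by age band multiplied by hazard ratios on the
individual's simulated risk factors (BMI with a quadratic term,
antihypertensive use, stroke history, diagnosed diabetes, plus an optional
covariate map).  A lifestyle intervention can additionally reduce the
dementia hazard directly, via CAIDE-score odds ratios for obesity,
hypertension and hyperlipidaemia, for a 20-year horizon.  Severity is
tracked on the MMSE (0-30); cognition at diagnosis is drawn from a Gamma
distribution of (30 - MMSE), and annual decline follows a piecewise-linear
spline regression on the previous score.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigError, InputError

MIN_DEMENTIA_AGE = 60.0


def _default_baseline_hazard_bands() -> list[tuple[float, float, float]]:
    # (age_low, age_high_exclusive, rate per 1000 person-years), both sexes.
    # Routine primary-care *diagnosis* incidence scale -- roughly half the
    # community true-incidence rates at younger old age, reflecting
    # under-diagnosis; the model describes diagnosed dementia.
    return [
        (60.0, 65.0, 0.6),
        (65.0, 70.0, 1.6),
        (70.0, 75.0, 4.1),
        (75.0, 80.0, 9.7),
        (80.0, 85.0, 18.0),
        (85.0, 90.0, 30.0),
        (90.0, 200.0, 42.0),
    ]


@dataclass
class DementiaIncidenceParams:
    """Diagnosis-hazard model: baseline by age band times covariate HRs.

    Hazard-ratio defaults are the published primary-care estimates for ages
    60-80: BMI 0.940 per kg/m^2 with quadratic term 1.003, antihypertensives
    0.876, stroke 1.781, diabetes 1.332.  The baseline hazard table is a
    configurable stand-in; absolute levels are a swappable input.
    """

    hr_bmi_per_unit: float = 0.940
    hr_bmi_sq_per_unit: float = 1.003
    hr_antihypertensives: float = 0.876
    hr_stroke: float = 1.781
    hr_diabetes: float = 1.332
    se_hr_bmi: float = 0.0038
    se_hr_bmi_sq: float = 0.0003
    se_hr_antihypertensives: float = 0.0296
    se_hr_stroke: float = 0.0394
    se_hr_diabetes: float = 0.0417
    bmi_reference: float = 28.0
    covariate_hrs: dict[str, float] = field(default_factory=dict)
    baseline_hazard_bands: list[tuple[float, float, float]] = field(
        default_factory=_default_baseline_hazard_bands)

    def validate(self) -> None:
        for name in ("hr_bmi_per_unit", "hr_bmi_sq_per_unit",
                     "hr_antihypertensives", "hr_stroke", "hr_diabetes"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be > 0")
        for hr in self.covariate_hrs.values():
            if hr <= 0:
                raise ConfigError("covariate hazard ratios must be > 0")
        for lo, hi, rate in self.baseline_hazard_bands:
            if rate < 0 or hi <= lo:
                raise ConfigError("invalid baseline hazard band")

    @classmethod
    def bands_from_csv(cls, path) -> list[tuple[float, float, float]]:
        """Load a hazard table CSV (age_low, age_high, sex, rate_per_1000py).

        Sex-specific rows are averaged (the shipped model is sex-equal)."""
        df = pd.read_csv(path)
        for c in ("age_low", "age_high", "rate_per_1000py"):
            if c not in df.columns:
                raise ConfigError(f"hazard table CSV missing column '{c}'")
        g = df.groupby(["age_low", "age_high"])["rate_per_1000py"].mean().reset_index()
        return [(float(r.age_low), float(r.age_high), float(r.rate_per_1000py))
                for r in g.itertuples()]

    def baseline_hazard(self, age):
        """Annual baseline diagnosis hazard at ``age`` (0 below age 60)."""
        age = np.asarray(age, dtype=float)
        h = np.full(age.shape, np.nan)
        h[age < MIN_DEMENTIA_AGE] = 0.0
        for lo, hi, rate in self.baseline_hazard_bands:
            h[(age >= lo) & (age < hi)] = rate / 1000.0
        if np.any(np.isnan(h)):
            raise ConfigError("no baseline dementia hazard for some ages")
        return h


def thin_relative_risk(bmi, on_antihypertensives, stroke_history,
                       diabetes_diagnosed, params: DementiaIncidenceParams,
                       covariate_flags: dict[str, object] | None = None):
    """Covariate hazard-ratio product of the diagnosis risk score.

    BMI enters per-unit with a quadratic term, centred at ``bmi_reference``
    so the baseline hazard is interpretable at the cohort centre.
    """
    bmi = np.asarray(bmi, dtype=float)
    ref = params.bmi_reference
    rr = (params.hr_bmi_per_unit ** (bmi - ref)
          * params.hr_bmi_sq_per_unit ** (bmi ** 2 - ref ** 2))
    rr = rr * np.where(np.asarray(on_antihypertensives, dtype=bool),
                       params.hr_antihypertensives, 1.0)
    rr = rr * np.where(np.asarray(stroke_history, dtype=bool), params.hr_stroke, 1.0)
    rr = rr * np.where(np.asarray(diabetes_diagnosed, dtype=bool), params.hr_diabetes, 1.0)
    if covariate_flags:
        for name, flag in covariate_flags.items():
            hr = params.covariate_hrs.get(name, 1.0)
            rr = rr * np.where(np.asarray(flag, dtype=bool), hr, 1.0)
    return rr


def dementia_diagnosis_probability(i, params: DementiaIncidenceParams) -> float:
    """Annual probability of dementia diagnosis for one individual.

    Zero below age 60; otherwise 1 - exp(-h0(age) * RR) with RR the
    covariate hazard-ratio product.
    """
    if not i.alive or i.dementia_diagnosed:
        raise InputError("individual must be alive and undiagnosed")
    if i.age < MIN_DEMENTIA_AGE:
        return 0.0
    h0 = params.baseline_hazard(np.asarray([i.age]))[0]
    rr = thin_relative_risk(
        i.bmi, i.on_antihypertensives, i.stroke_history, i.diabetes_diagnosed,
        params,
        covariate_flags={"depression": i.depression, "anxiety": i.anxiety,
                         "nsaids": i.nsaid_use},
    )
    return float(-np.expm1(-h0 * float(rr)))


@dataclass
class DementiaRiskReductionParams:
    """Direct intervention effect on dementia incidence via CAIDE odds ratios.

    An individual moved below a risk-factor threshold (obesity BMI > 30,
    hypertension SBP > 140 mm Hg, hyperlipidaemia TC > 6.5 mmol/L) by the
    intervention contributes 1/OR to the hazard-rate ratio (odds ratios are
    applied as rate ratios under a rare-event approximation); the effect
    lasts ``horizon`` years from intervention start.
    """

    or_obese: float = 2.296
    or_hypertension: float = 2.206
    or_hyperlipidemia: float = 1.879
    se_or_obese: float = 0.3034
    se_or_hypertension: float = 0.3238
    se_or_hyperlipidemia: float = 0.3161
    bmi_obese: float = 30.0
    sbp_hypertension: float = 140.0
    tc_hyperlipidemia: float = 6.5
    horizon: float = 20.0

    def validate(self) -> None:
        for name in ("or_obese", "or_hypertension", "or_hyperlipidemia"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be > 0")
        if self.horizon <= 0:
            raise ConfigError("horizon must be > 0")


def caide_relative_risk(control_profile, treated_profile, year_since_start,
                        params: DementiaRiskReductionParams):
    """Hazard-rate ratio for the treated vs control risk-factor profiles.

    Profiles are (bmi, sbp, total_chol) triples (scalars or arrays) already
    adjusted for the intervention taper.  For each factor the exponent is
    [treated above threshold] - [control above threshold] in {-1, 0, +1}, so
    moving below a threshold multiplies the hazard by 1/OR.  Returns 1 after
    the risk-reduction horizon.
    """
    c_bmi, c_sbp, c_tc = (np.asarray(v, dtype=float) for v in control_profile)
    t_bmi, t_sbp, t_tc = (np.asarray(v, dtype=float) for v in treated_profile)
    rr = np.ones(np.broadcast(c_bmi, t_bmi).shape)
    for orf, thr, c, t in (
        (params.or_obese, params.bmi_obese, c_bmi, t_bmi),
        (params.or_hypertension, params.sbp_hypertension, c_sbp, t_sbp),
        (params.or_hyperlipidemia, params.tc_hyperlipidemia, c_tc, t_tc),
    ):
        d = (t > thr).astype(float) - (c > thr).astype(float)
        rr = rr * orf ** d
    expired = np.asarray(year_since_start, dtype=float) > params.horizon
    rr = np.where(expired, 1.0, rr)
    return rr if rr.shape else float(rr)


@dataclass
class MMSEOnsetParams:
    """Gamma model of (30 - MMSE) at diagnosis.

    Defaults give mean MMSE at diagnosis 21 with SD 5 (shape 3.24,
    scale 25/9), matching population-based summary data on cognition at
    dementia diagnosis; onset cognition is independent of age, sex and
    health status.
    """

    shape: float = 3.24
    scale: float = 25.0 / 9.0

    def validate(self) -> None:
        if self.shape <= 0 or self.scale < 0:
            raise ConfigError("gamma shape must be > 0 and scale >= 0")


def mmse_from_gamma_draw(g):
    """Map a Gamma(shape, scale) deficit draw to an MMSE score in [0, 30]."""
    return np.clip(30.0 - np.asarray(g, dtype=float), 0.0, 30.0)


def sample_mmse_at_diagnosis(params: MMSEOnsetParams, rng: np.random.Generator,
                             size=None):
    """Draw MMSE at diagnosis: clamp(30 - Gamma(shape, scale), 0, 30)."""
    if params.scale == 0.0:
        g = np.zeros(size) if size is not None else 0.0
    else:
        g = rng.gamma(params.shape, params.scale, size=size)
    out = mmse_from_gamma_draw(g)
    return out if size is not None else float(out)


@dataclass
class MMSEProgressionParams:
    """Annual rate of MMSE change: piecewise-linear spline on previous score.

    rate = intercept + b_pm1*PM1 + b_pm2*PM2 + b_pm3*PM3 + b_age*age
           + b_prev_rate*prev_rate,
    with PM1 = min(prev, 9), PM2 = clamp(prev - 9, 0, 9),
    PM3 = clamp(prev - 18, 0, 12) (knots at 9 and 18).
    """

    intercept: float = -5.4663
    b_pm1: float = -0.4299
    b_pm2: float = -0.0042
    b_pm3: float = 0.1415
    b_age: float = 0.0747
    b_prev_rate: float = -0.0791
    se_intercept: float = 0.9836
    se_pm1: float = 0.0597
    se_pm2: float = 0.0410
    se_pm3: float = 0.0487
    se_age: float = 0.0127
    se_prev_rate: float = 0.0317

    def validate(self) -> None:
        for f in ("intercept", "b_pm1", "b_pm2", "b_pm3", "b_age", "b_prev_rate"):
            if not np.isfinite(getattr(self, f)):
                raise ConfigError(f"{f} must be finite")


def annual_mmse_change(prev_mmse, age, prev_rate, params: MMSEProgressionParams):
    """Annual MMSE rate of change (score/year; negative = decline)."""
    prev = np.asarray(prev_mmse, dtype=float)
    if np.any((prev < 0) | (prev > 30)):
        raise InputError("prev_mmse outside [0, 30]")
    pm1 = np.minimum(prev, 9.0)
    pm2 = np.clip(prev - 9.0, 0.0, 9.0)
    pm3 = np.clip(prev - 18.0, 0.0, 12.0)
    return (params.intercept + params.b_pm1 * pm1 + params.b_pm2 * pm2
            + params.b_pm3 * pm3 + params.b_age * np.asarray(age, dtype=float)
            + params.b_prev_rate * np.asarray(prev_rate, dtype=float))


@dataclass
class MortalityHRs:
    """Dementia hazard ratios on all-cause mortality by age at death."""

    hr_60_84: float = 4.54
    hr_85_plus: float = 2.77
    se_60_84: float = 0.1276
    se_85_plus: float = 0.0784

    def validate(self) -> None:
        if self.hr_60_84 <= 0 or self.hr_85_plus <= 0:
            raise ConfigError("dementia mortality HRs must be > 0")


# Severity banding.  Cost bands use the costing study's MMSE ranges
# (mild 21-26, moderate 10-20, severe 0-9); utility bands use the
# Alzheimer utility study's ranges (21-25, 15-20, 10-14, 0-9; no decrement
# from 26).  The one-point mismatch at MMSE 26 (mild-dementia cost, no
# utility decrement) is in the source tables and is preserved literally.

def severity_band(mmse) -> tuple[str, str]:
    """Map an MMSE score to (cost_band, utility_band) labels."""
    m = float(mmse)
    if not 0.0 <= m <= 30.0:
        raise InputError("mmse outside [0, 30]")
    if m >= 27.0:
        cost = "none"
    elif m >= 21.0:
        cost = "mild"
    elif m >= 10.0:
        cost = "moderate"
    else:
        cost = "severe"
    if m >= 26.0:
        utility = "none"
    elif m >= 21.0:
        utility = "21-25"
    elif m >= 15.0:
        utility = "15-20"
    elif m >= 10.0:
        utility = "10-14"
    else:
        utility = "0-9"
    return cost, utility
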