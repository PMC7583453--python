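"""Annual-cycle simulation engine, scenario comparisons, subgroups, PSA.

The engine simulates a cohort in annual cycles until death or an age cap,
as a two-arm comparison (diabetes prevention programme vs no programme)
under three scenarios: ``no_dementia`` (dementia machinery off),
``dementia_only`` (dementia incidence, progression, costs, utilities and
mortality active, no direct intervention effect on dementia), and
``reduced_dementia_risk`` (additionally, the CAIDE-based hazard reduction in
the intervention arm).

Common random numbers: both arms and all scenarios share an identical
cohort and identical per-event random streams.  Each event type draws from
its own named stream, and every stream draws a full cohort-sized vector
every cycle regardless of state, so that activating dementia (or the
intervention) never perturbs the draws of any other event type.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import dementia as dem
from .comorbidity import ComorbidityParams, death_probability, hazard_to_probability
from .economics import incremental_net_benefit
from .errors import ConfigError, InputError
from .params import ParameterSet, draw_psa_sample
from .population import Individual
from .trajectories import FACTOR_BOUNDS, FACTORS, intervention_offset

SCENARIOS = ("no_dementia", "dementia_only", "reduced_dementia_risk")
ARMS = ("control", "dpp")

# Named random streams (order fixes the stream identities).
STREAMS = ("trajectory", "death", "diabetes", "cvd", "stroke", "cancer",
           "osteoarthritis", "depression", "chf", "dementia", "mmse_onset")
_PSA_STREAM_KEY = 101


@dataclass
class ScenarioConfig:
    scenario: str
    arm: str
    seed: int
    age_cap: float = 100.0

    def validate(self) -> None:
        if self.scenario not in SCENARIOS:
            raise ConfigError(f"unknown scenario '{self.scenario}'")
        if self.arm not in ARMS:
            raise ConfigError(f"unknown arm '{self.arm}'")
        if self.age_cap <= 0:
            raise ConfigError("age_cap must be > 0")


@dataclass
class ArmResult:
    """Per-arm discounted per-person means and lifetime event counts."""

    scenario: str
    arm: str
    seed: int
    n: int
    total_cost: float
    health_cost: float
    social_cost: float
    dementia_cost: float
    cardiovascular_cost: float
    intervention_cost: float
    qalys: float
    life_years: float
    diabetes_diagnoses_per_1000: float
    cvd_events_per_1000: float
    dementia_diagnoses_per_1000: float
    counters: dict = field(default_factory=dict)
    discounted_cost_by_year: np.ndarray | None = None
    ledger: pd.DataFrame | None = None


@dataclass
class IncrementalResult:
    """Arm differences (dpp - control) and incremental net benefit."""

    scenario: str
    control: ArmResult
    dpp: ArmResult
    delta_total_cost: float
    delta_health_cost: float
    delta_social_cost: float
    delta_dementia_cost: float
    delta_cardiovascular_cost: float
    delta_qalys: float
    delta_life_years: float
    delta_diabetes_per_1000: float
    delta_cvd_events_per_1000: float
    delta_dementia_per_1000: float
    inb: float

    @property
    def cumulative_incremental_cost_by_year(self) -> np.ndarray:
        """Cumulative discounted incremental cost per person by model year."""
        return np.cumsum(self.dpp.discounted_cost_by_year
                         - self.control.discounted_cost_by_year)


class _Cohort:
    """Column-array view of a list of individuals."""

    def __init__(self, cohort: list[Individual]):
        self.n = len(cohort)
        self.ids = np.array([i.id for i in cohort])
        self.age0 = np.array([i.age for i in cohort], dtype=float)
        self.male = np.array([i.sex == "male" for i in cohort])
        self.smoker = np.array([i.smoking == "current" for i in cohort])
        self.antihtn = np.array([i.on_antihypertensives for i in cohort])
        self.anxiety = np.array([i.anxiety for i in cohort])
        self.nsaid = np.array([i.nsaid_use for i in cohort])
        self.eq5d = np.array([i.baseline_eq5d for i in cohort], dtype=float)
        self.factors0 = {f: np.array([getattr(i, f) for i in cohort], dtype=float)
                         for f in FACTORS}
        self.diab0 = np.array([i.diabetes_diagnosed for i in cohort])


def _mmse_utility_multiplier(mmse, diagnosed, mults: dict[str, float]):
    m = np.where(np.isnan(mmse), 30.0, mmse)
    mult = np.select(
        [m >= 26.0, m >= 21.0, m >= 15.0, m >= 10.0],
        [1.0, mults["21-25"], mults["15-20"], mults["10-14"]],
        default=mults["0-9"],
    )
    return np.where(diagnosed, mult, 1.0)


def _dementia_band_costs(mmse, diagnosed, band_costs: dict[str, float]):
    m = np.where(np.isnan(mmse), 30.0, mmse)
    cost = np.select(
        [m >= 27.0, m >= 21.0, m >= 10.0],
        [0.0, band_costs["mild"], band_costs["moderate"]],
        default=band_costs["severe"],
    )
    return np.where(diagnosed, cost, 0.0)


def run_arm(cohort: list[Individual], config: ScenarioConfig,
            params: ParameterSet, record_ledger: bool = False) -> ArmResult:
    """Simulate one arm over the cohort's lifetime and aggregate outcomes.

    Deterministic for a fixed ``config.seed``: the same seed yields
    bit-identical results, and the control and intervention arms consume
    identical random streams.
    """
    config.validate()
    params.validate()
    if len(cohort) == 0:
        raise InputError("cohort must be non-empty")
    c = _Cohort(cohort)
    n = c.n
    rngs = {s: np.random.default_rng(
        np.random.SeedSequence(entropy=config.seed, spawn_key=(k,)))
        for k, s in enumerate(STREAMS)}

    dementia_on = config.scenario != "no_dementia"
    caide_on = (config.scenario == "reduced_dementia_risk"
                and config.arm == "dpp")
    is_dpp = config.arm == "dpp"
    com: ComorbidityParams = params.comorbidity
    r = params.economics.discount_rate
    deltas = params.intervention.deltas
    duration = params.intervention.duration

    age = c.age0.copy()
    alive = np.ones(n, dtype=bool)
    cf = {f: c.factors0[f].copy() for f in FACTORS}  # counterfactual path
    diab = c.diab0.copy()
    cvd_ever = np.zeros(n, dtype=bool)
    stroke = np.zeros(n, dtype=bool)
    flags = {name: np.zeros(n, dtype=bool) for name in com.other_conditions}
    dem_dx = np.zeros(n, dtype=bool)
    mmse = np.full(n, np.nan)
    prev_rate = np.zeros(n)

    led = {k: np.zeros(n) for k in ("health", "social", "dementia",
                                    "cardiovascular", "intervention")}
    qalys = np.zeros(n)
    life_years = np.zeros(n)
    first_diab = np.zeros(n, dtype=bool)
    first_cvd = np.zeros(n, dtype=bool)
    counters = {"thin_evaluations": 0, "caide_applications": 0}
    mults = params.utilities.condition_multipliers
    cc = params.costs.condition_costs

    # Frozen CAIDE risk ratio: year-1 full-effect profile vs baseline.
    if caide_on and params.caide_mode == "frozen":
        frozen_rr = dem.caide_relative_risk(
            (c.factors0["bmi"], c.factors0["sbp"], c.factors0["total_chol"]),
            (np.clip(c.factors0["bmi"] + deltas["bmi"], *FACTOR_BOUNDS["bmi"]),
             np.clip(c.factors0["sbp"] + deltas["sbp"], *FACTOR_BOUNDS["sbp"]),
             np.clip(c.factors0["total_chol"] + deltas["total_chol"],
                     *FACTOR_BOUNDS["total_chol"])),
            1.0, params.caide)
        frozen_rr = np.asarray(frozen_rr)

    n_cycles = int(np.ceil(config.age_cap - c.age0.min()))
    cost_by_year = np.zeros(n_cycles)
    ledger_rows = [] if record_ledger else None

    for t in range(n_cycles):
        year = t + 1
        # Fixed draw schedule: every stream draws for everyone every cycle.
        z = rngs["trajectory"].standard_normal((n, len(FACTORS)))
        u = {s: rngs[s].random(n) for s in STREAMS[1:-1]}
        if params.mmse_onset.scale > 0:
            g_onset = rngs["mmse_onset"].gamma(
                params.mmse_onset.shape, params.mmse_onset.scale, n)
        else:
            g_onset = np.zeros(n)
            rngs["mmse_onset"].random(n)  # keep the stream advancing

        # 1. Mortality (dies this cycle -> accrues nothing this cycle).
        # Ages of the already-dead keep incrementing past the lifetable;
        # clamp the lookup age (their draws are discarded anyway).
        p_death = death_probability(
            np.minimum(age, config.age_cap), c.male, cvd_ever, flags["cancer"], diab,
            dem_dx if dementia_on else np.zeros(n, dtype=bool), com,
            params.dementia_mortality.hr_60_84,
            params.dementia_mortality.hr_85_plus)
        alive = alive & ~(u["death"] < p_death)

        # 2. Metabolic factors: counterfactual drift + intervention taper.
        if t > 0:
            for k, f in enumerate(FACTORS):
                rule = params.trajectories.drift[f]
                sd = params.trajectories.residual_sd[f]
                lo, hi = FACTOR_BOUNDS[f]
                cf[f] = np.clip(cf[f] + rule.drift(age) + sd * z[:, k], lo, hi)
        cur = {}
        for f in FACTORS:
            off = intervention_offset(deltas[f], year, duration) if is_dpp else 0.0
            cur[f] = np.clip(cf[f] + off, *FACTOR_BOUNDS[f])

        # 3. Comorbid events (absorbing flags).
        new_diab = (alive & ~diab
                    & (cur["hba1c"] >= com.diabetes_hba1c_threshold)
                    & (u["diabetes"] < com.diabetes_detection_prob))
        diab = diab | new_diab
        first_diab = first_diab | new_diab
        h_cvd = com.cvd.hazard(age, cur["sbp"], c.male, c.smoker, diab,
                               cur["total_chol"], cur["hdl_chol"])
        cvd_event = alive & (u["cvd"] < hazard_to_probability(h_cvd))
        first_cvd = first_cvd | cvd_event
        cvd_ever = cvd_ever | cvd_event
        stroke = stroke | (cvd_event & (u["stroke"] < com.stroke_fraction))
        for name, rule in com.other_conditions.items():
            p_cond = hazard_to_probability(rule.hazard(age))
            flags[name] = flags[name] | (alive & ~flags[name] & (u[name] < p_cond))

        # 4. Dementia: progression for the diagnosed, then new diagnoses.
        new_dem = np.zeros(n, dtype=bool)
        if dementia_on:
            prog = alive & dem_dx
            if prog.any():
                rate = dem.annual_mmse_change(mmse[prog], age[prog],
                                              prev_rate[prog],
                                              params.mmse_progression)
                mmse[prog] = np.clip(mmse[prog] + rate, 0.0, 30.0)
                prev_rate[prog] = rate
            cand = alive & ~dem_dx & (age >= dem.MIN_DEMENTIA_AGE)
            counters["thin_evaluations"] += int(cand.sum())
            h0 = params.dementia_incidence.baseline_hazard(age)
            # The diagnosis risk score sees the counterfactual BMI path in
            # both arms: the intervention has no direct metabolic effect on
            # dementia incidence -- arm differences arise only through the
            # diabetes and stroke flags, plus (in the reduced-risk scenario)
            # the explicit CAIDE hazard reduction below.
            rr = dem.thin_relative_risk(
                cf["bmi"], c.antihtn, stroke, diab, params.dementia_incidence,
                covariate_flags={"depression": flags["depression"],
                                 "anxiety": c.anxiety, "nsaids": c.nsaid})
            h_dem = h0 * rr
            if caide_on and year <= params.caide.horizon:
                if params.caide_mode == "frozen":
                    rr_caide = frozen_rr
                else:
                    rr_caide = np.asarray(dem.caide_relative_risk(
                        (cf["bmi"], cf["sbp"], cf["total_chol"]),
                        (cur["bmi"], cur["sbp"], cur["total_chol"]),
                        year, params.caide))
                h_dem = h_dem * rr_caide
                counters["caide_applications"] += int(cand.sum())
            p_dem = -np.expm1(-h_dem)
            new_dem = cand & (u["dementia"] < p_dem)
            mmse[new_dem] = dem.mmse_from_gamma_draw(g_onset[new_dem])
            prev_rate[new_dem] = 0.0
            dem_dx = dem_dx | new_dem

        # 5. Accrual for survivors (discounted at cycle index t).
        util = c.eq5d * params.utilities.age_multiplier(age)
        for name, flag in (("cvd_history", cvd_ever), ("cancer", flags["cancer"]),
                           ("osteoarthritis", flags["osteoarthritis"]),
                           ("depression", flags["depression"]),
                           ("chf", flags["chf"])):
            util = util * np.where(flag, mults.get(name, 1.0), 1.0)
        if dementia_on:
            util = util * _mmse_utility_multiplier(
                mmse, dem_dx, params.utilities.mmse_multipliers)

        cardio = np.where(cvd_event, cc.get("cvd_event_year", 0.0),
                          np.where(cvd_ever, cc.get("cvd_history_year", 0.0), 0.0))
        other = diab * cc.get("diabetes", 0.0)
        for name in ("cancer", "osteoarthritis", "depression", "chf"):
            other = other + flags[name] * cc.get(name, 0.0)
        if dementia_on:
            dem_h = _dementia_band_costs(mmse, dem_dx, params.costs.dementia_health)
            dem_s = _dementia_band_costs(mmse, dem_dx, params.costs.dementia_social)
            dem_h = dem_h + new_dem * params.costs.dementia_diagnosis_cost
        else:
            dem_h = dem_s = np.zeros(n)
        # The programme fee is charged at enrolment (cycle 0) for every
        # participant; a cycle-0 death does not refund it.
        interv = np.full(n, params.intervention.cost) if (is_dpp and t == 0) \
            else np.zeros(n)
        health = cardio + other + dem_h
        social = dem_s

        disc = 1.0 / (1.0 + r) ** t
        a = alive.astype(float)
        led["health"] += (a * health + interv) * disc
        led["social"] += a * social * disc
        led["dementia"] += a * (dem_h + dem_s) * disc
        led["cardiovascular"] += a * cardio * disc
        led["intervention"] += interv * disc
        qalys += a * util * disc
        life_years += a
        cost_by_year[t] = float(np.sum(a * (health + social) + interv) * disc) / n

        if record_ledger:
            ledger_rows.append(pd.DataFrame({
                "id": c.ids, "year": t, "age": age, "alive": alive,
                "cost_health": (a * health + interv) * disc,
                "cost_social": a * social * disc,
                "cost_dementia": a * (dem_h + dem_s) * disc,
                "cost_cardiovascular": a * cardio * disc,
                "cost_intervention": interv * disc,
                "utility": np.where(alive, util, 0.0),
                "qaly_discounted": a * util * disc,
            }))

        # 6. Ageing and the age cap.
        age = age + 1.0
        alive = alive & (age < config.age_cap)

    total = led["health"] + led["social"]
    result = ArmResult(
        scenario=config.scenario, arm=config.arm, seed=config.seed, n=n,
        total_cost=float(total.mean()),
        health_cost=float(led["health"].mean()),
        social_cost=float(led["social"].mean()),
        dementia_cost=float(led["dementia"].mean()),
        cardiovascular_cost=float(led["cardiovascular"].mean()),
        intervention_cost=float(led["intervention"].mean()),
        qalys=float(qalys.mean()),
        life_years=float(life_years.mean()),
        diabetes_diagnoses_per_1000=float(first_diab.sum()) * 1000.0 / n,
        cvd_events_per_1000=float(first_cvd.sum()) * 1000.0 / n,
        dementia_diagnoses_per_1000=float(dem_dx.sum()) * 1000.0 / n,
        counters=counters,
        discounted_cost_by_year=cost_by_year,
        ledger=pd.concat(ledger_rows, ignore_index=True) if record_ledger else None,
    )
    return result


def compare_arms(cohort: list[Individual], scenario: str,
                 params: ParameterSet, seed: int,
                 record_ledger: bool = False) -> IncrementalResult:
    """Two-arm comparison (DPP vs no DPP) with common random numbers."""
    ctrl = run_arm(cohort, ScenarioConfig(scenario, "control", seed),
                   params, record_ledger)
    dpp = run_arm(cohort, ScenarioConfig(scenario, "dpp", seed),
                  params, record_ledger)
    dq = dpp.qalys - ctrl.qalys
    dc = dpp.total_cost - ctrl.total_cost
    return IncrementalResult(
        scenario=scenario, control=ctrl, dpp=dpp,
        delta_total_cost=dc,
        delta_health_cost=dpp.health_cost - ctrl.health_cost,
        delta_social_cost=dpp.social_cost - ctrl.social_cost,
        delta_dementia_cost=dpp.dementia_cost - ctrl.dementia_cost,
        delta_cardiovascular_cost=dpp.cardiovascular_cost - ctrl.cardiovascular_cost,
        delta_qalys=dq,
        delta_life_years=dpp.life_years - ctrl.life_years,
        delta_diabetes_per_1000=(dpp.diabetes_diagnoses_per_1000
                                 - ctrl.diabetes_diagnoses_per_1000),
        delta_cvd_events_per_1000=(dpp.cvd_events_per_1000
                                   - ctrl.cvd_events_per_1000),
        delta_dementia_per_1000=(dpp.dementia_diagnoses_per_1000
                                 - ctrl.dementia_diagnoses_per_1000),
        inb=incremental_net_benefit(dq, dc, params.economics.willingness_to_pay),
    )


def age_band(lo: float, hi: float):
    """Subgroup predicate: lo <= baseline age < hi."""
    return lambda i: lo <= i.age < hi


def hba1c_band(lo: float, hi: float):
    """Subgroup predicate: lo <= baseline HbA1c <= hi."""
    return lambda i: lo <= i.hba1c <= hi


def run_subgroups(cohort: list[Individual], scenario: str,
                  params: ParameterSet, bands: dict, seed: int) -> pd.DataFrame:
    """Two-arm comparison within each subgroup band.

    ``bands`` maps a label to a predicate over an Individual.  An empty band
    yields a flagged row (n = 0, NaN outcomes), not a failure.
    """
    rows = []
    for label, pred in bands.items():
        members = [i for i in cohort if pred(i)]
        if not members:
            rows.append({"band": label, "n": 0, "empty": True,
                         "delta_total_cost": np.nan, "delta_qalys": np.nan,
                         "inb": np.nan})
            continue
        inc = compare_arms(members, scenario, params, seed)
        rows.append({"band": label, "n": len(members), "empty": False,
                     "delta_total_cost": inc.delta_total_cost,
                     "delta_qalys": inc.delta_qalys, "inb": inc.inb})
    return pd.DataFrame(rows)


@dataclass
class PSAResult:
    samples: pd.DataFrame          # one row per PSA sample
    ceac: pd.DataFrame             # columns: lambda, probability
    lambda_grid: np.ndarray


def run_psa(cohort: list[Individual], scenario: str, params: ParameterSet,
            n_samples: int, lambda_grid=None, seed: int = 0) -> PSAResult:
    """Probabilistic sensitivity analysis with a CEAC.

    Each sample redraws the uncertain parameters from their distributions
    and recomputes the two-arm increment on the same cohort with the same
    event streams (so the CEAC isolates parameter uncertainty).
    CEAC(lambda) is the fraction of samples with positive net benefit.
    """
    if n_samples < 1:
        raise InputError("n_samples must be >= 1")
    if lambda_grid is None:
        lambda_grid = np.arange(0.0, 50001.0, 2500.0)
    lambda_grid = np.asarray(lambda_grid, dtype=float)
    if lambda_grid.size == 0:
        raise InputError("lambda_grid must be non-empty")
    param_rng = np.random.default_rng(
        np.random.SeedSequence(entropy=seed, spawn_key=(_PSA_STREAM_KEY,)))
    rows = []
    for s in range(n_samples):
        ps = draw_psa_sample(params, param_rng)
        inc = compare_arms(cohort, scenario, ps, seed)
        rows.append({"sample": s, "delta_total_cost": inc.delta_total_cost,
                     "delta_qalys": inc.delta_qalys, "inb": inc.inb})
    samples = pd.DataFrame(rows)
    dq = samples["delta_qalys"].to_numpy()
    dc = samples["delta_total_cost"].to_numpy()
    prob = [(lam * dq - dc > 0).mean() for lam in lambda_grid]
    ceac = pd.DataFrame({"lambda": lambda_grid, "probability": prob})
    return PSAResult(samples=samples, ceac=ceac, lambda_grid=lambda_grid)
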