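# Methods

`dppsim` is an annual-cycle, individual-level state-transition model of a
diabetes prevention programme (DPP) in the English impaired-glucose-
regulation (IGR) population, extended with dementia as an explicit health
outcome. This note records the model, its assumptions, the defaults and
why they were chosen, and what the synthetic-data generator does and does
not emulate.

## Cohort generation

The eligible population (HbA1c 6.0–6.4%, age ≥ 16, no diagnosed diabetes)
is synthesised from published summary statistics rather than survey
microdata. Continuous risk factors (age, BMI, SBP, total and HDL
cholesterol, HbA1c) are drawn from a **Gaussian copula**: a multivariate
normal on the latent scale with a configurable correlation matrix (defaults
BMI–SBP 0.20, BMI–HbA1c 0.15, SBP–age 0.30, others 0), mapped through each
factor's marginal. Age uses a normal(57.1, 17.6) truncated to [16, 90];
HbA1c a normal(6.2, 0.15) truncated to the eligibility window; the
remaining factors are normal at their published means/SDs, clipped to wide
physiological ranges. Binary attributes (44.7% male, 10.7% non-white,
19.1%/29.4% current/past smokers, 26.4% treated hypertension) are
independent Bernoulli draws. Socioeconomic band (uniform 1–5), anxiety
(10%) and NSAID use (15%) are configurable prevalences used only by the
optional covariate map of the dementia risk score.

Baseline EQ-5D follows the rule 0.95 − 0.003·(age − 40)₊ plus
normal(0, 0.1) individual noise, clamped to [0, 1]. This is a stand-in for
the survey-derived utility distribution; it is configurable and its exact
shape does not drive any comparative result (it scales both arms equally).

What the generator does **not** emulate: survey design weights, non-normal
marginal shapes (e.g. BMI skew), region/ethnicity-specific risk-factor
structure, and any real joint distribution beyond the assumed copula
correlations. Passing tests therefore show internal consistency with the
published marginal summaries, not fidelity to individual-level survey data.

## Metabolic trajectories and the intervention

Each factor drifts annually by `intercept + age_slope·age +
post60_shift·[age ≥ 60]` plus normal residual noise, clamped to a
physiological range (BMI [13, 70], SBP [70, 250], TC [1.5, 15], HDL
[0.3, 5], HbA1c [4, 20]). Shipped drifts: BMI +0.05/yr before 60,
−0.05/yr after; SBP +0.5/yr; HbA1c +0.02/yr; TC +0.01/yr before 60,
−0.02/yr after; HDL flat. Residual SDs: BMI 0.3, SBP 3.0, TC 0.15,
HDL 0.05, HbA1c 0.10 — the HbA1c value reflects realistic within-person
year-to-year variability in the IGR range and governs how quickly the
cohort disperses across the diabetes diagnostic threshold.

The intervention applies its full metabolic effect in year 1 and **tapers
linearly** to zero over the 5-year duration of effect:
`offset(y) = Δ·max(0, (D+1−y)/D)`. A linear taper is the simplest monotone
interpolant consistent with "the gap narrows over time and is gone after
5 years"; a step shape is obtainable by configuration of the duration.
Each individual carries the counterfactual factor path explicitly and the
treated path is counterfactual + offset, so the two arms coincide exactly
from year 6 — the "return to the level they would have been" contract is
structural, not statistical.

## Comorbidity stand-ins

The host physiology around the dementia adaptation is deliberately
simplified and every piece is configurable:

- **Diabetes**: diagnosed when current HbA1c ≥ 6.5% and an annual
  detection draw (p = 0.5) succeeds, approximating routine GP testing.
- **CVD**: one log-linear annual hazard, centred at 1%/yr for a
  57-year-old non-smoking woman at SBP 130 without diabetes, with
  log-hazard coefficients 0.55/decade of age, 0.12/10 mm Hg SBP, 0.30 male,
  0.40 current smoker, 0.50 diabetes (lipid coefficients available,
  default 0). A fraction 0.25 of events are strokes. These are calibration
  knobs, not epidemiological claims.
- **Other conditions** (cancer, osteoarthritis, depression, heart
  failure): age-exponential incidence rules with plausible base rates.
- **Mortality**: a synthetic Gompertz–Makeham lifetable
  q(age) = min(0.7, 0.0002 + e^(−10.5+0.087·age)), identical by sex with a
  1.3 male hazard excess (a national table can be supplied as CSV), with
  hazard-scale multipliers for prevalent conditions: CVD 2.0, cancer 2.0,
  diabetes 1.6 — magnitudes in line with UK cohort estimates — and the
  dementia hazard ratios below. Hazard ⇄ probability conversions use
  p = 1 − e^(−h) throughout.

Costs accumulate additively across conditions (accepting some double
counting); utility decrements multiply.

## Dementia

**Incidence.** From age 60, annual diagnosis hazard = baseline hazard by
age band × hazard-ratio product on the individual's simulated risk
factors: BMI 0.940 per kg/m² with quadratic term 1.003 (centred at the
cohort-mean reference BMI 28, so the baseline hazard is interpretable at
the cohort centre), antihypertensive use 0.876, stroke history 1.781,
diagnosed diabetes 1.332, plus an optional covariate map (SES, smoking,
sex, lipids, depression, anxiety, NSAIDs) defaulting to 1. The shipped
baseline table is on the **routine primary-care diagnosis scale**
(0.6/1.6/4.1/9.7/18/30/42 per 1000 person-years for bands 60–64 … 90+),
roughly half the community true-incidence rates at younger old ages,
because the modelled quantity is a recorded diagnosis; with the shipped
defaults the lifetime diagnosed incidence is ≈ 210/1000, close to the
published ≈ 240/1000 for this population. The table is a named, swappable
CSV input.

The risk score is evaluated on the **counterfactual BMI path in both
arms**: the intervention has no direct metabolic effect on dementia
incidence, so in the dementia-only scenario arm differences arise only
through the diabetes and stroke flags, and the direct effect is carried
exclusively by the CAIDE channel below. (Feeding the treated BMI into the
score would create an implicit direct effect — the quadratic BMI term
alone would cut the hazard ~14% during the effect years.)

**Direct risk reduction (CAIDE).** The intervention multiplies the
dementia hazard by ∏ OR_f^(d_f), d_f = [treated above threshold] −
[control above threshold] ∈ {−1, 0, +1}, with odds ratios obesity 2.296
(BMI > 30), hypertension 2.206 (SBP > 140), hyperlipidaemia 1.879
(TC > 6.5), applied as hazard-rate ratios under a rare-event
approximation, for a 20-year horizon. Default `caide_mode: frozen` fixes
the ratio at its year-1 (full-effect) value for the whole horizon,
matching the stated 20-year risk reduction; `recompute` re-evaluates it
each cycle on taper-adjusted factors (under which it returns to 1 once the
metabolic effect has tapered, i.e. after year 5, unless threshold
crossings persist).

**Cognition.** MMSE at diagnosis is 30 − Gamma(3.24, 25/9), clamped to
[0, 30] (mean 21, SD 5), independent of age, sex and health. Annual
change: rate = −5.4663 − 0.4299·PM1 − 0.0042·PM2 + 0.1415·PM3 +
0.0747·age − 0.0791·prev_rate with spline basis PM1 = min(prev, 9),
PM2 = clamp(prev−9, 0, 9), PM3 = clamp(prev−18, 0, 12). The diagnosis year
uses the onset score with zero accrued progression; progression starts the
following cycle with prev_rate initialised to 0.

**Severity bands.** Costs: mild MMSE 21–26 (£3103 health + £5674 social),
moderate 10–20 (£8293 + £22,703), severe 0–9 (£9841 + £23,466); MMSE ≥ 27
retains the diagnosis but accrues no dementia cost. Utility multipliers:
0.93 (21–25), 0.725 (15–20), 0.710 (10–14), 0.478 (0–9), none from 26.
The one-point mismatch at MMSE 26 (mild cost, no utility decrement) is in
the source tables and is preserved literally. The one-off diagnosis cost
defaults to £0 (configuration hook).

**Mortality.** Diagnosed dementia multiplies the all-cause mortality
hazard by 4.54 at ages 60–84 and 2.77 from age 85 (the attenuated
oldest-age estimate).

## Economics

NHS + personal social services perspective, 2016–17 GBP. Annual utility =
baseline EQ-5D × age multiplier × condition multipliers × MMSE multiplier;
the age multiplier is max(0.4, 1 − 0.0002·(age−40)₊²), a swappable
stand-in for the published age-decrement curve. Non-dementia condition
multipliers default to CVD 0.90, cancer 0.85, osteoarthritis 0.90,
depression 0.85, heart failure 0.85; annual condition costs to CVD
event-year £5000 / history-year £800, diabetes £1800, cancer £5000,
osteoarthritis £800, depression £500, heart failure £2000 — stand-ins of
UK-plausible magnitude. Discounting is 1/(1.035)^t with cycle 0
undiscounted; whether the first year should be discounted is a convention,
fixed here as undiscounted. No half-cycle correction (events at cycle
start, annual cycles). An individual who dies accrues nothing in the death
cycle (`accrue_death_year` flag available); the £270 programme fee is the
exception — it is charged at enrolment and not refunded. Net benefit:
INB = λ·ΔQALY − ΔCost, λ = £20,000/QALY.

## Engine and random-number design

Cycle order: mortality draw → metabolic update → comorbid events →
dementia progression/diagnosis → cost and QALY accrual → ageing (cap at
age 100). Both arms and all scenarios share one cohort and one dedicated
random stream per event type; every stream draws a full cohort-sized
vector every cycle regardless of state, so activating dementia or the
intervention never perturbs any other event's draws. This common-random-
numbers design makes arm differences estimable at much smaller n than
independent arms would need. Scenario gating is instrumented: counters
record how often the dementia risk score and the CAIDE ratio were
evaluated, and tests assert the gating contract on them.

Per-1000 event counts are lifetime **first-event** counts per 1000
simulated persons (a dementia or diabetes diagnosis counts once per
person); whether recurrent events should be counted is unspecified in the
source material, and the first-event convention is documented here.

## Sensitivity analysis

PSA draws are independent across parameters: metabolic effects normal with
their reported SEs; hazard/odds ratios (dementia incidence, CAIDE,
dementia mortality) lognormal with SEs on the printed scale; MMSE
progression coefficients normal; dementia costs gamma at 10% SE (band
order re-sorted to keep mild ≤ moderate ≤ severe); utility multipliers
beta-matched at 10% SE. The simulation streams are held fixed across
samples, so the acceptability curve isolates parameter uncertainty.
Defaults (500 samples, overridable) are sized for desk-scale runs; the
reported analyses in `scripts/acceptance.py` use 200 samples × 2000
individuals for the CEAC and 10,000 individuals for deterministic
comparisons — sizes chosen so a full reproduction completes in about a
minute on one core.

## Numerical and degenerate cases

Probabilities are computed with `expm1`/`log1p` for accuracy at small
hazards. Gamma onset with scale 0 degenerates to MMSE 30 (the stream
still advances to preserve draw alignment). Empty subgroup bands yield
flagged rows, not failures. Negative hazards, out-of-range MMSE,
non-PSD correlation matrices and unknown configuration keys raise typed
errors (`InputError` vs `ConfigError`).

## Known limitations

- The non-dementia disease models are single-equation stand-ins; absolute
  cost levels (especially dementia social care, which dominates lifetime
  costs at high incidence) should not be read as forecasts. Comparative,
  within-model contrasts are the supported use.
- Dementia subtypes, behavioural/functional scales (NPI, ADL/IADL) and
  post-diagnosis treatment are out of scope by design.
- The CAIDE odds-ratio → rate-ratio conversion assumes rare events; at the
  oldest ages dementia diagnosis is not rare and the reduction is
  correspondingly approximate.
- Odds ratios, hazard ratios and trial effects are treated as transportable
  across populations and constant over time.
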