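# Methods

## Model structure

The model is a discrete-time (annual-cycle) individual-level state-transition
simulation with memory. Each simulated woman starts CVD-free between ages 30
and 54 and is followed until death or age 100. Within a cycle, competing
risks are resolved sequentially: (1) non-CVD death, (2) a CVD event given
survival, (3) the event subtype. Annual probabilities are small (well under
0.1 for almost all person-cycles), so the ordering bias of the sequential
scheme is second-order. A first-ever event is drawn from a nine-way subtype
split (MI, unstable angina, ischaemic stroke, haemorrhagic stroke, TIA, PVD,
CHF, other CHD, other CVD death); recurrent events are non-fatal stroke,
non-fatal MI or CVD death. `other_CVD_death` and `cvd_death` end the
trajectory in the event cycle; all other subtypes are survivable. The event
count and the cycle of the first event are tracked per individual and feed
the recurrent-risk equation, the utility rules and the management costs.

## Risk equations

Both equations are Cox-form "risk calculator" tables: a linear predictor
over centred covariates, `lp = Σ β_j (x_j − x̄_j)/s_j`, and a baseline
survival at the equation's horizon, giving `p_h = 1 − S0^exp(lp)`;
`p_1 = 1 − (1 − p_h)^(1/h)` converts to the annual cycle (constant hazard
within the horizon). Declared transforms cover indicator predictors
(current/ex smoker, diabetes), the TC/HDL ratio, age-by-diabetes and
age-by-SBP interactions (computed on covariates centred at the main
effects' reference values) and log time since the first event (whole years,
minimum 1).

* First-ever CVD: 5-year horizon, female coefficient set of the published
  New Zealand primary-care (PREDICT-type) equation. Predictors not carried
  by the simulated population (ethnicity, family history, atrial
  fibrillation, baseline medication) are held at their centering values,
  i.e. at the derivation cohort's reference profile.
* Recurrent CVD: 10-year horizon, secondary-prevention (SMART-type) form
  restricted to the simulated state (age, smoking, diabetes, SBP, TC, HDL,
  log years since first event, the last with a negative coefficient so risk
  is highest soon after the index event).

The bundled coefficients are best-effort reconstructions from the source
publications (tagged `source-publication` in the config); users with access
to an exact transcription can drop it into the YAML without touching code.

Background non-CVD mortality is a step function of age (female all-cause
mortality net of the CVD-attributable share); it is looked up on attained
age every cycle.

## Population and risk-factor dynamics

Baseline characteristics are drawn independently per individual from
marginals conditioned on age band only (the survey sources publish
marginals, not joint distributions): age-band masses with integer ages
uniform within band; deprivation quintile; smoking status; diabetes; SBP
band (value = band midpoint plus optional uniform within-band jitter,
pragmatic edges 95/175 mmHg for the open-ended bands); TC and HDL from
normals truncated at physiologic floors (2.0 and 0.4 mmol/L). During the
simulation age advances one year per cycle and SBP/TC/HDL drift by
age-band-specific annual increments, so the risk equations are re-evaluated
each cycle on attained age and drifted risk factors.

## Intervention

The programme is delivered annually for five years at A$335.63/person/year
and lowers the *effective* SBP used in risk computation by 3.16 mmHg while
the woman is adherent and CVD-free; the stored SBP trajectory is never
altered. Delivery, and with it cost and effect, stops permanently at the
first CVD event. `adherence_years` shortens both cost and effect (the
extreme-value analysis sets it to 1); `effect_years` can extend the effect
beyond the delivery period for the threshold analysis, without extending
cost.

## Valuation

Utilities: a CVD-free cycle uses the age curve of the general female
population (0.84 at 30–39 down to 0.68 at 80+; older ages clamp to the
oldest band). After one event the weight is the minimum of the age-curve
value and the subtype's post-event utility (a multiplicative combination is
switchable); unstable angina has no published post-event weight and keeps
the age-curve value. After two or more events the generic post-CVD weight
0.626 applies. The post-ischaemic-stroke weight is the mRS-distribution
weighted average of the mRS-level utilities (0.429 under the default
weights, which are an assumption — the source's mRS distribution is not
printed). The post-event weight applies from the event cycle onward
(switchable to next-cycle).

Costs: the programme cost in adherent cycles; the subtype's acute
hospitalisation cost in the event cycle; the most recent subtype's annual
management cost in every later cycle (a recurrent event switches the
management cost to its subtype; routing all post-recurrence management to
the generic post-CVD cost is switchable). PVD management uses the composite
A$5,062 figure rather than the severity split.

Discounting: every payoff in cycle t is credited mid-cycle,
`(1+r)^−(t+0.5)`, r = 3%/year; life-years count 1 per cycle lived and 0.5
in the death cycle, QALYs weight those fractions by the cycle's utility.
ICERs are only reported as ratios in the trade-off quadrant; dominance is
labelled instead of mixing signs.

## Common random numbers and reproducibility

Each individual owns a random stream keyed by `(master_seed, id)` and
consumes exactly one uniform per purpose (death / event / subtype) per
cycle, pre-drawn for the full cycle budget. Both arms therefore see
identical randomness, results are independent of cohort ordering or
batching, and a zero-effect intervention reproduces the usual-care arm bit
for bit. With the base-case −3.16 mmHg effect the hazard ratio during the
five effect years is exp(0.0137·3.16) ≈ 1.044, so only a few first events
per 10,000 women are flipped; the QALY increment is the sum of a handful of
individual trajectory differences and its Monte-Carlo error is of the same
order as its mean even at n = 10,000. The ICER should accordingly be read
as order-of-magnitude (clearly above the A$50,000 threshold), which the
probabilistic and deterministic sensitivity analyses make explicit. Paired
sampling is still the right design: unpaired arms would add between-arm
noise of roughly ±45 events per 10,000.

## Analyses

* Base case: n = 10,000 paired lifetime run (a few seconds on one CPU).
* Subgroups: the age marginal restricted to 30–40, 40–50 or 50–55 and
  renormalised; conditional tables untouched.
* One-way DSA: each parameter with a configured plausible range (utility
  and acute-cost ranges, discount rate 0–5%, effect −6.32 to −0.01 mmHg,
  effect duration 1–10 years, horizon via the age cap, programme start age)
  is set to each endpoint with the base master seed, so endpoint runs
  differ from the base only through the varied parameter; entries are
  sorted by ICER span, with dominance at an endpoint ranked as maximal.
* PSA: cost parameters draw from gamma and utility parameters from beta
  distributions matched to the published mean/SD by method of moments
  (infeasible beta moments are rejected by name). Sampled parameters do
  not enter transition probabilities, so each draw's paired simulation at
  the same seed would reproduce identical event trajectories; the
  implementation therefore simulates once (default inner cohort 2,000) and
  re-prices the fixed trajectories per draw (default 2,000 draws), which is
  exact and keeps the CEAC cheap. The CEAC is the fraction of draws with
  non-negative net monetary benefit over a WTP grid (A$0–200,000).
* Threshold: integer sweep over the effect duration (bisection to 1e-4
  relative tolerance for continuous parameters), returning the smallest
  value whose ICER reaches the WTP threshold, or none.
* Extreme value: adherence (cost and effect) limited to the first year.
* Budget impact: eligible-N × per-capita annual cost × a 5-year annuity
  with the first payment undiscounted, plus the per-person lifetime
  discounted cost offset scaled to the eligible population.

## What the synthetic cohort does and does not emulate

The generator reproduces age-conditional marginals and their drift with
age. It does not model within-age-band correlation between risk factors
(e.g. smoking–SBP association), secular trends, intervention uptake
heterogeneity, or measurement error in the survey inputs. Passing tests
therefore demonstrate correct model mechanics and faithful parameter
plumbing under the configured marginals, not calibration of absolute CVD
incidence to any national registry — the first-ever equation is
deliberately extrapolated beyond its derivation range (ages 30–74) to the
age cap, which inflates lifetime event counts relative to sources that
treat risk as fixed at programme entry.

## Numerical choices and degenerate inputs

Cycle length is fixed at one year. Probabilities are clipped to [0,1]; a
horizon probability of exactly 1 converts to an annual probability of 1
with a warning. Categorical draws use a fixed subtype order and inverse-CDF
lookup, so results are invariant to dictionary ordering. Config validation
happens entirely at load (mass sums to 1 within 1e-9, DSA ranges
bracketing base values, PSA SDs attached to existing parameters); the
engine assumes valid inputs. An empty cohort, zero-width sensitivity
ranges, degenerate (single-mass) distributions and all-zero hazards are
supported and covered by tests.

## Known limitations

* Risk-equation transcription is best-effort from the source publications;
  absolute event counts inherit that uncertainty.
* No within-year event timing; no case fatality within survivable subtypes
  (fatalities are carried entirely by the two fatal categories).
* The recurrent-event split is a single age-invariant table.
* No societal perspective (productivity), currency conversion or CPI
  indexing.
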