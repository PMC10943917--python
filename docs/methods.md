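# Methods

## Model structure

The model couples a 12-week decision tree to a two-state Markov cohort
process. Cycle 1 is the assessment period: deaths are drawn first (mortality
is independent of health state), then surviving patients split into
responders (probability `response_prob`, a ≥ 50% MMD reduction) and
non-responders. Responders who experience adverse-event-driven
discontinuation (`ae_discontinuation_prob_cycle1`) join the non-responders in
the *discontinued* state; the rest are *on treatment*. From cycle 2 on,

```
on(k)   = on(k-1) · (1 − d_lt) · (1 − q_k)
disc(k) = disc(k-1) · (1 − q_k) + on(k-1) · (1 − q_k) · d_lt
dead(k) = dead(k-1) + q_k · alive(k-1)
```

where `d_lt` is the long-term per-cycle discontinuation probability and `q_k`
the background mortality of cycle `k`. Occupancies are conserved to 1e-12 by
construction and checked in tests. Discontinued patients stay on best
supportive care: they keep their band's resource use and acute medication but
accrue no preventive-drug cost.

**Horizon discretisation.** Ten years (3,652.5 days) is not a multiple of the
84-day cycle; the trace runs 43 full cycles plus one partial cycle whose
accruals (costs, QALYs, migraine days, drug) are weighted by the remaining
fraction 0.4821, so discounted time ends exactly at 10 years. No half-cycle
correction is applied: outcomes attach to states at cycle end, which is also
when MMD levels are defined.

**Mortality.** The cohort ages continuously (`age = 41 + (k−1)·84/365.25`);
the annual probability qx is looked up at the floor age, mixed 80.5%/19.5%
female/male, and converted to the cycle's actual length via
`1 − (1−q)^(days/365.25)`. Ages beyond the life table reuse its last row.
Migraine itself adds no mortality.

## State-level MMD assignment and calibration

Published results report *arm-average* MMD trajectories, not the MMD of the
responder state. `calibrate_responder_mmd` inverts

```
arm_avg(k) = p_on(k) · mmd_resp(k) + (1 − p_on(k)) · baseline
```

at each printed target week (occupancies do not depend on MMD, so the
inversion is exact: the forward trace reproduces each target to 1e-9), with
piecewise-constant values between targets. Non-responders and discontinued
patients revert to baseline MMD — a package convention, exposed as
`discontinued_mmd`, since post-discontinuation levels are not published.
An explicit `responder_mmd` overrides calibration; with neither targets nor
an override, the responder state sits at half the baseline (the responder
definition itself).

For the chronic-migraine placebo arm no feasible calibration exists: at a
30.26%/cycle long-term discontinuation the on-treatment share decays
geometrically to ~0, so the published 10-year arm-average (18.32 MMD, barely
below the 18.66 baseline) cannot be produced by any responder MMD in
[0, baseline] under baseline reversion. The packaged CM placebo default
therefore fixes the responder state at half the baseline (9.33 MMD); the CM
erenumab arm calibrates to its published 10-year mean (13.48 MMD) at the
final cycle. Episodic-migraine arms calibrate to the printed week-12/24/108
trajectories.

**Calibration is structural.** Sensitivity analyses (PSA, tornado, scenarios)
freeze the MMD assignment at the base case. Re-calibrating per draw would pin
the arm-average trajectory back to its targets and thereby cancel the very
perturbation being studied (and turns infeasible for draws that lower the
response probability).

## Utilities and adverse events

Utility is linear in MMD, `u = 0.85 − 0.0176·m` (SE of the slope 0.0035),
clamped to [0, 1]; the validator rejects coefficient sets that go negative
within the modelled 0–28 MMD spectrum. The published per-band utility ranges
are descriptive; the linear model is normative (at 28 MMD it gives 0.3572,
rounding to the published ≥ 21-MMD band floor 0.36).

Adverse-event disutilities come from a 15-item catalogue (utility loss and SE
per event). Each arm's incidence-weighted loss `Σ incidence·loss` is charged
**once**, pro-rated to the cycle length (`loss · 84/365.25` QALYs), against
the cycle-1 survivors: incidences are assessment-period quantities and a
recurring charge would double-count. Whether the original analysis applied
the loss once or per cycle is not stated; one-off is the conservative
reading. Per-arm incidences themselves are not published — the packaged
values are plausible trial-scale defaults and feed only the (small) AE
decrement and its PSA spread.

## Costs

Direct costs per cycle and MMD band (floor rule for fractional MMD; bands
0 / 1–3 / 4–7 / 8–14 / 15+) are the sum of
`unit_cost · units · fraction_of_patients` over the band's resource rows,
plus acute medication at the midpoint of the published 12-week range (the
endpoints feed the tornado instead; the no-migraine band is a point value).
The published resource table concatenates units and percentages; the packaged
reconstruction (e.g. hospitalisation —/5%/7%/7%/17%, emergency
—/29%/54%/74%/72%) is stored in the config precisely so users can override
it. The hospital pharmacy visit (€5.89) accrues only in arms flagged
`hospital_dispensed`.

Preventive drug cost accrues to the whole surviving cohort in cycle 1
(everyone is on drug during the assessment) and to the on-treatment state
afterwards. The statutory price discount (default 7.5%, configurable) applies
to hospital-dispensed (ex-factory) prices only. Real acquisition prices are
not public: the packaged €500/cycle (erenumab) and €30/cycle (topiramate) are
flagged placeholders, and every model construction warns about them.

Indirect costs (societal perspective only) value absent days at one daily
labour cost and presenteeism days at half a day (configurable):
`2847.10 / 22 · (1 − 0.127) ≈ €112.98/day`. The wage-division-then-
unemployment-adjustment order is a package reading of "adjusted to 22 working
days, considering an unemployment rate"; it scales expected earnings per
calendar worker. Work-loss day counts come from linear regressions on MMD
(3-month recall window, rescaled by 84/90 to the cycle, floored at 0). The
underlying regression coefficients are not published; the packaged defaults
(absenteeism 0.3 + 0.45·MMD, presenteeism 0.5 + 0.95·MMD days/3 months) were
chosen once to the order of magnitude implied by the published societal cost
totals. A WPAI-based presenteeism variant backs the corresponding scenario.

Migraine days accrue undiscounted (the published 10-year MD totals are raw
counts); QALYs and costs are discounted at 3%/year on continuous time
`(1+r)^(−t_k)`.

## Synthetic data

`SyntheticGeneratorSpec`/`generate_trial` emulate the *structure* the
analysis assumes about the unavailable trial-level data: MMD from a truncated
normal on [0, 28]; observed utility linear in MMD with truncated Gaussian
noise; MIDAS absent days as negative-binomial counts (overdispersed
nonnegative integers) around a linear mean; WPAI presenteeism linear with
Gaussian noise clipped to [0, 100]; per-arm Bernoulli adverse-event flags.
One seed drives one generator stream: identical spec + seed ⇒ byte-identical
tables. The generator deliberately does **not** emulate trial dropout, visit
schedules, EQ-5D scoring mechanics, or within-patient longitudinal
correlation — so passing recovery tests show the estimators are correct under
the assumed structure, not that the published coefficients are right for real
patients.

`generate_life_table` produces a Gompertz-like table (qx growing
geometrically with age, male excess factor 1.8, capped at 1 with a warning);
the packaged `lifetable_synthetic.csv` uses base 0.0008 at 41, growth
1.09/year — roughly the order of a Western European adult table. It is a
synthetic stand-in, not national statistics.

## Regressions

Utility-by-MMD is ordinary least squares (slope reported as a positive
decrement; coefficient covariance kept for multivariate-normal PSA
sampling). Work-loss fits use heteroscedasticity-robust (HC1) standard
errors because count-model variance grows with the mean; confidence
intervals use the t distribution. Designs with fewer than 3 observations or
a constant MMD column are rejected.

## Sensitivity analysis

**Tornado.** Each named parameter (or parameter group — a unit cost is
perturbed jointly across bands) is set to 0.8× and 1.2× its base value, with
probabilities capped at 1 (warned); the outcome is net monetary benefit
`λ·ΔQALY − ΔCost` at the €30,000 threshold by default (ICER is available but
unstable under sign changes). Entries are sorted by swing, ties broken by
name, so the ordering is permutation-invariant.

**PSA.** Families follow the published mapping — beta for probabilities and
utility losses, lognormal for odds ratios, gamma for resource costs and
discontinuation rates, multivariate normal for regression coefficient pairs —
parameterised by moment matching (beta: `ν = m(1−m)/se² − 1`; gamma:
`shape = (m/se)²`, `rate = m/se²`; lognormal: `σ² = ln(1 + se²/m²)`,
`μ = ln m − σ²/2`). A zero SE fixes the parameter. No covariances are
published, so coefficient pairs default to diagonal covariance, and the
response probability and odds ratio are drawn independently. The intervention
response is re-derived on the odds scale from the sampled comparator response
and odds ratio. After sampling, probabilities are clamped to [0, 1] and the
utility slope to `[0, u0/28]` (keeping the line admissible; a > 3.6 SD
event). Resource-cost SEs are not published; the gamma SE defaults to 20% of
the mean, configurable. One root seed spawns one child stream per iteration,
so iteration i is reproducible regardless of the total count. The CEAC
reports `P(λ·ΔQALY − ΔCost > 0)` on a €0–50,000 grid in €100 steps.

The published CEAC crossings (≈ €20,700 EM, ≈ €5,800 CM) depend on the
unpublished drug prices and covariances and are reproduced qualitatively
only.

## Verification sizes and numerical choices

Test problem sizes are package choices balancing power against runtime: the
microsimulation oracle uses 200,000 patients × 5 randomised parameter sets
(agreement within 3 binomial Monte Carlo SEs at six checkpoints per state);
parameter-recovery calibration uses 200 replicates of n = 500 (95% CI
coverage required in 93–97%); sampler moment checks use 50,000 draws.
Occupancy conservation is asserted to 1e-12, calibration round-trips to
1e-9, cost-category additivity to 1e-9. A month is 30.4375 days for the
MMD→migraine-day conversion; a year is 365.25 days throughout.

## Known limitations

- Headline cost totals and ICERs depend on placeholder drug prices.
- Table-reconstruction and baseline-reversion conventions (documented above)
  are package readings of ambiguously published inputs.
- No treatment switching, re-challenge, adherence waning, caregiver or
  out-of-pocket costs; no EVPI/EVSI; no correlation modelling beyond the
  diagonal-covariance multivariate normals.
- The synthetic life table and synthetic trial data are structural stand-ins;
  results on real populations require the corresponding national inputs.
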