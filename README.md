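# migraine-cea

Cost-effectiveness modelling of preventive migraine treatment: a 12-week
decision tree feeding a two-state Markov cohort model over a 10-year horizon,
with monthly-migraine-day (MMD) driven utilities and costs, deterministic and
probabilistic sensitivity analysis, and a synthetic patient-level data
generator so the whole pipeline runs without any external data.

The package is aimed at health economists and HTA analysts evaluating a
CGRP-pathway monoclonal antibody (erenumab) against oral prophylaxis
(topiramate, for episodic migraine) or best supportive care (placebo, for
chronic migraine) from the perspective of a national health system, with an
optional societal perspective that adds productivity losses.

## Model

All patients start preventive treatment. At the end of the 12-week assessment
a patient is a *responder* (≥ 50% reduction in MMD) or not. Non-responders and
responders who stop for adverse events move to the *discontinuation* state;
tolerating responders stay *on treatment* and afterwards leave only through a
long-term per-cycle discontinuation probability or background mortality
(general-population life table mixed by sex, 80.5% female; migraine carries no
excess mortality). Discontinuation is absorbing except for death.

Outcomes attach to the MMD level of each state at the end of each 84-day
cycle $k$, weighted by state occupancy and discounted at rate $r$:

- utility: $u(m) = u_0 - b\,m$ with $u_0 = 0.85$ and $b = 0.0176$ per MMD,
  clamped to $[0, 1]$, plus a one-off incidence-weighted adverse-event
  disutility in cycle 1;
- QALYs: $\sum_k u(m_k)\,\tfrac{84}{365.25}\,(1+r)^{-t_k}$ per state;
- migraine days (undiscounted): $m_k \times 84 / 30.4375$ per person-cycle;
- costs: per-band healthcare resource use, acute medication (range midpoint),
  preventive drug while on treatment, and — under the societal perspective —
  absenteeism/presenteeism days from linear work-loss regressions valued at
  the daily labour cost $\frac{\text{wage}}{\text{working days}}(1 - \text{unemployment})$.

Two strategies are compared by incremental cost-effectiveness ratio
$\mathrm{ICER} = \Delta C / \Delta E$ against a €30,000/QALY threshold, and by
cost per migraine day avoided. The probabilistic analysis draws every
uncertain parameter from a moment-matched distribution (beta for
probabilities and utility losses, lognormal for odds ratios, gamma for costs
and discontinuation rates, multivariate normal for regression coefficients)
and summarises 1000 Monte Carlo iterations as a cost-effectiveness
acceptability curve.

Drug acquisition prices are not public: the packaged defaults are
**placeholders** (flagged, with a startup warning) and headline cost totals
depend on them.

## Worked example

```python
from migraine_cea import CostEffectivenessModel

results = CostEffectivenessModel.from_defaults("EM").fit()
print(results.summary())
```

```
Cost-effectiveness results
==========================================================================
population: EM   perspective: healthcare   horizon: 10 y   discount: 3.0%/3.0%
--------------------------------------------------------------------------
arm                 cost (EUR)     QALYs   migraine days
topiramate              16,243    5.9177           1,083
erenumab                20,200    6.1553             899
--------------------------------------------------------------------------
incremental cost:        3,956 EUR
incremental QALYs:      0.2376
MDs avoided:               185
ICER:             16,651 EUR/QALY
cost per MD avoided: 21.40 EUR/MD
dominance: none
==========================================================================
NOTE: placeholder drug prices in arms: erenumab, topiramate
```

Read: over 10 years a cohort member on erenumab accrues 6.1553 QALYs and 899
cumulative migraine days against 5.9177 QALYs and 1,083 days on topiramate;
at the placeholder prices the extra €3,956 buys 0.2376 QALYs, i.e. €16,651
per QALY gained — below the €30,000 threshold. Sensitivity analyses hang off
the same object: `results.psa()`, `results.tornado()`,
`results.scenario("societal")`, `results.plot_ceac()`.

The same pipeline is scriptable from the shell:

```sh
migraine-cea run   --population EM --out out/run
migraine-cea psa   --population CM --n 1000 --seed 7 --out out/psa
migraine-cea dsa   --population EM --out out/dsa
migraine-cea synth --n 500 --seed 1 --out out/synth
```

Every results directory carries a `manifest.json`, the resolved parameter
set, and plain delimited tables with a sidecar schema description.

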