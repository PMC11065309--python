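# ceemod

Decision-analytic cost-effectiveness and cost-utility modelling of an
electronic automated advisory vital-signs monitoring and notification system
versus routine spot-check monitoring for adults on general hospital wards,
from the perspective of the UK NHS.

The package is aimed at health economists and methodologists who want a
tested, reproducible implementation of a one-shot decision-tree model with
lifetime payoffs: parameter estimation from patient-level data, a
deterministic base case, probabilistic sensitivity analysis (PSA), and
scenario/subgroup machinery, driven by a single plain-text parameter file.

## The model

Each arm's cohort discharges into one of three states — *no event*, a
non-fatal *principal serious adverse event* (seven categories: acute
myocardial infarction, pulmonary embolism, acute pulmonary oedema,
respiratory failure, severe sepsis, emergency ICU admission, cardiopulmonary
arrest), or *inpatient death*.  Each discharge state `s` carries a published
lifetime cost `C_s` and discounted quality-adjusted life expectancy
`QALE_s`; death contributes zero for both.  Per arm,

```
E[QALE] = p_no_event·QALE_ne + p_event·Σ_e π_e·QALE_e + p_death·0
E[cost] = hospital episode cost + analogous lifetime-cost expectation
```

where the no-event payoffs are a ward-mix weighted average (56% pulmonology)
of the respiratory and gastroenterology ward profiles, and states cheaper
than "no event" (pulmonary embolism) carry the no-event cost forward.  The
lifetime incremental cost-effectiveness ratio is

```
ICER = (COST_auto − COST_standard) / (QALE_auto − QALE_standard)
```

with dominance declared when the new strategy is cheaper *and* more
effective.  Device purchase prices are annualized by straight-line
depreciation or equivalent annual cost (annuity factor `(1−(1+r)^−n)/r`) and
spread over annual throughput `(365/LOS)·beds`.  The PSA redraws every
uncertain input (Dirichlet for probability vectors, Gamma for costs, Normal
truncated at zero for QALEs) and summarizes the draws as cost-effectiveness
plane quadrants, net monetary benefit `λ·ΔQ − ΔC`, and the
cost-effectiveness acceptability curve.

A synthetic patient-level cohort generator stands in for the original ward
research database (no public accession exists), reproducing its covariate
marginals and the adjusted regression targets, so the estimation stage
(negative-binomial event counts, gamma GLM costs, multinomial-logit
discharge states, bootstrap central ranges) can be validated end to end.

## Worked example

```python
import ceemod

params = ceemod.load_default_parameters()     # bundled base-case inputs
result = ceemod.evaluate_base_case(params)

from ceemod.reporting import render_base_case_text
print(render_base_case_text(result))
```

prints

```
quantity                intervention       control   incremental
hospital_cost_gbp           2,046.99      2,059.16        -12.17
lifetime_cost_gbp          17,641.39     17,685.05        -43.65
total_cost_gbp             19,688.38     19,744.21        -55.82
events_per_patient            0.0666        0.0933       -0.0267
qale                          7.3704        7.3417        0.0286
lifetime verdict: dominant (NMB at 20,000: 628.28)
```

Read: automated monitoring costs £12.17 less per inpatient episode, avoids
0.0267 serious adverse events per patient, and over a lifetime horizon saves
£55.82 while gaining 0.0286 QALYs (~10 days of perfect health) — it
*dominates* standard care, with a net monetary benefit of about £628 per
patient at the £20,000/QALY threshold.  The same numbers are available from
the command line via `ceemod basecase`, and the other stages via
`ceemod simulate|estimate|device-cost|psa|sensitivity|scenario-sd|run`.

A probabilistic run:

```python
from ceemod.psa import PSAConfig, run_psa, ceac_at
psa = run_psa(params, PSAConfig(n_draws=10_000, seed=1))
print(round(ceac_at(psa, 20_000), 3))   # 0.81 — P(cost-effective at £20k/QALY)
```

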