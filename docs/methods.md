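# Methods

## Model structure and assumptions

The economic model is a one-shot decision tree with lifetime payoffs, not a
Markov state-transition model: every patient admitted to one of two general
wards (gastroenterology, pulmonology) is monitored either by an automated
advisory vital-signs monitoring and notification system (intervention) or by
routine spot-check monitoring (control), and leaves the inpatient episode in
one of three discharge branches — no serious adverse event, a non-fatal
principal serious adverse event (seven categories), or inpatient death.
Where a patient experiences multiple events, the discharge state is the
event with the worst health state; we order severity by ascending
quality-adjusted life expectancy (QALE).  Each discharge state carries a
published lifetime cost and a discounted QALE; inpatient death contributes
zero cost and zero QALYs beyond the episode.

Key conventions:

* **No-event state.** A convex combination of the two ward chronic-condition
  profiles, weighted by the pulmonology admission share (default 0.56, an
  explicit input rather than a constant).
* **Cost carry-forward.** When an event state's lifetime cost would fall
  below the no-event cost, the no-event cost is carried forward.  In the
  base-case inputs this applies to pulmonary embolism only, which has no
  published lifetime cost of its own and is flagged `carry_forward` in the
  parameter file.
* **Discounting.** Inpatient episode costs are undiscounted (horizon under a
  year); lifetime costs and QALYs are inputs already discounted at 3.5%/yr
  and scaled to the model population's life expectancy (17.74 years).  The
  discount rate remains configurable because it also enters equivalent-
  annual-cost device annualization.
* **Hospital episode costs are inputs.** The per-arm adjusted means
  (£2,046.99 / £2,059.16, device cost included) come from patient-level
  regressions; the engine treats them as opaque inputs and never recomputes
  them from tariff components.
* **Life-years saved.** The short-term cost-per-life-year view is an
  extrapolated convention, `(p_death_control − p_death_intervention) ×
  life expectancy`, and is labelled as such.

## Device costing

Annual device cost = annualized fixed price + variable sensor cost.  Fixed
price is annualized by straight-line depreciation (price / product life,
default 5 years) or by equivalent annual cost (price / annuity factor at the
discount rate; 4.515 for 5 years at 3.5%).  Variable cost (intervention
only) is `cableless rate × annual patients × sensor price`, one sensor per
monitored patient episode by default (`sensors_per_patient` is exposed
because per-episode sensor consumption is not observable).  Annual patient
throughput is `(365 / mean LOS) × beds × occupancy`, used unrounded; 100%
occupancy and 0% interest are the stated base-case assumptions, with
occupancy exposed as a knob.  The threshold analysis exploits that the
per-patient device cost is affine in its inputs: while the intervention
saves money during the episode, its device cost can rise by exactly the
magnitude of that saving before cost-neutrality.

## Probabilistic sensitivity analysis

Each of the (default) 10,000 replications redraws:

| Input | Distribution |
|---|---|
| discharge-state probabilities, per arm | Dirichlet(effective counts), e.g. (3579, 24, 184) |
| principal-event distribution, per arm | Dirichlet(fitted concentrations) |
| lifetime state costs | Gamma, mean = point estimate, CV = `sd_fraction` |
| state QALEs | Normal, sd = `sd_fraction` × mean, truncated at 0 by resampling |
| episode costs and event rates, per arm | Gamma moment-matched to mean and 95% central range (sd = width/3.92) |

`sd_fraction` defaults to 0.2 (scenarios 0.1 and 0.4 are provided by
`scenarios.scenario_sd`, holding the seed fixed across scenarios).  Design
choices where the method was genuinely open:

* **Dirichlet, not compound multinomial.** "Dirichlet-multinomial" inputs
  are sampled as probability vectors from a Dirichlet with the printed
  counts/concentrations — the standard conjugate PSA practice; compound
  multinomial resampling is available behind `dirichlet_multinomial=True`.
* **Degenerate concentrations.** The adjusted multinomial-logit fit can
  yield concentrations totalling essentially zero; draws fall back to the
  point estimates when the total is below 1e-6.
* **Shared health-state draws.** Both arms discharge into the same health
  states, so each replication draws one cost and one QALE per state, shared
  across arms; arm-specific probability vectors and episode costs are drawn
  independently.  This correlation structure reproduces the published
  incremental central ranges closely.
* **Episode-cost uncertainty** is published only as mean plus bootstrap
  central range; we sample a gamma moment-matched to those (costs are
  positive and right-skewed).  The acceptability probabilities therefore
  carry a little method uncertainty beyond Monte-Carlo error, reflected in
  the tolerance bands of the acceptance tests.
* **Device inputs are fixed** in the PSA (resource-use inputs are point
  values by design).

The CEAC is the fraction of draws with positive net monetary benefit,
`λ·ΔQ − ΔC > 0`, over a £0–£50,000 grid.  At λ=0 it equals P(ΔC<0); as λ→∞
it approaches P(ΔQ>0).

## Synthetic cohort generator

The generator emulates the ward population the model inputs were estimated
from; the real research database is not publicly accessible.  Emulated
features (defaults): cohort 3,787 (1,894/1,893 per arm); age from a scaled
Beta(3.874, 2.250) on [17, 100] calibrated to median 71 and IQR 59–81; 52%
female; 56% pulmonology; NEWS on admission from a discretized negative
binomial matched to mean 3.15 and sd 2.82, clipped to [0, 20]; per-arm gamma
length of stay (means 8.62/8.90 days, shape 1.3 — spread is a free knob);
gamma episode costs with log-linear covariate and any-event effects,
normalized per arm to the adjusted means; modest log-scale covariate
gradients on event risk (age +0.012/yr, female +0.10, pulmonology +0.08,
NEWS +0.16/point) and cost, chosen as plausible magnitudes since the true
gradients are not published — the per-arm normalization makes the headline
targets insensitive to them.

Event counts are a genuine gamma-Poisson (negative-binomial) model with a
log-link covariate structure.  Two calibrations tie counts and discharge
states together so patient records are internally consistent
(`event_count > 0` iff the patient died or has a principal event):

1. the per-arm intercept is normalized so the marginal mean count equals the
   configured target (0.0666/0.0933) exactly in expectation, and
2. the per-arm NB dispersion is solved (1-d root find) so the expected
   zero-count probability equals the arm's no-event probability
   (0.9451/0.9395); discharge state is then derived from the count, with
   death vs survival decided by the configured conditional and the surviving
   principal-event category drawn from the per-arm distribution.

Zero-inflation relative to the Poisson floor guarantees the overdispersion
(variance > mean) the estimation stage assumes.  ICU days are drawn only for
emergency-ICU discharges (gamma, mean 3.5 days) as a realism garnish.

**What the generator does not emulate:** vital-sign time series, alarms and
escalation dynamics; the real correlation structure between NEWS, events,
LOS and costs beyond the configured log-linear gradients; readmissions;
within-ward clustering.  Passing recovery tests therefore show that the
estimation stage is unbiased *under the assumed data-generating structure*,
not that the original regressions were.

## Estimation

Negative-binomial (NB2) regression for event counts, gamma GLM with log
link for episode costs, multinomial logit for discharge states — each on
arm + age + sex + ward + NEWS, via statsmodels.  "Adjusted" per-arm means
are recycled predictions: predict every patient under each arm
counterfactually and average (with no covariates this reduces to raw arm
means).  NEWS enters as a continuous covariate; banding is left to subgroup
definitions.  Uncertainty uses the percentile bootstrap (95% central range
= 2.5th/97.5th percentiles), with failed resamples redrawn up to a retry
cap.  The within-survivor principal-event distribution is reported as
normalized empirical frequencies (the categories are far too sparse for a
stable seven-way logit); how to turn them into Dirichlet concentrations for
the PSA is left to configuration.

## Numerical choices, problem sizes, and limitations

* Monetary values are stored at full precision; rounding (GBP 2 dp, QALYs
  and probabilities 4 dp) happens only in rendered reports.
* The cableless dominance boundary is found by bisection to ±0.001; the
  short-term incremental cost is affine in the rate so the crossing is
  unique.
* The dispersion root-find brackets α in [1e-6, 1e4] and returns the
  Poisson limit when the zero-probability target sits below the Poisson
  floor.
* Validation study sizes: the parameter-recovery check runs 200 replicate
  cohorts of n = 3,787; generator convergence checks use 50,000 patients;
  PSA checks use 10,000 draws (seeded, so all checks are deterministic).
  Stochastic assertions use ~3 Monte-Carlo SE bounds: count distributions
  are heavy-tailed and tighter bounds reject too often on a single seeded
  draw.
* Pipeline seeds fan out from one run seed via `numpy.random.SeedSequence`
  spawning, one 31-bit child per stage, so stages are independently
  reproducible.
* Maintenance/training costs, staffing opportunity costs and readmission
  are out of scope, as in the source analysis.  Subgroup analyses accept
  per-stratum parameter sets as inputs; stratum-specific secondary
  parameters (age/sex-adjusted QALEs) must be supplied by the user since the
  underlying reference tables are not bundled.
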