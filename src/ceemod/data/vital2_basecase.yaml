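# Base-case model inputs: automated vital-signs monitoring and notification
# system (intervention) vs routine spot-check monitoring (control) on two
# general wards of a UK district general hospital.
#
# Discharge-state and principal-event probabilities are adjusted estimates
# from patient-level data (n = 3787; multinomial logit adjusting for arm,
# age, sex, ward, and NEWS on admission).  Lifetime costs and QALEs are
# published estimates (GBP 2020/21), discounted at 3.5% and scaled to a
# population life expectancy of 17.74 years.  Dirichlet counts/concentrations
# and the Gamma/Normal specs parameterize the probabilistic sensitivity
# analysis.

probabilities:
  intervention:
    no_event: 0.9451
    event_survive: 0.0064
    inpatient_death: 0.0485
    dirichlet_counts: [3579, 24, 184]
  control:
    no_event: 0.9395
    event_survive: 0.0106
    inpatient_death: 0.0499
    dirichlet_counts: [3558, 40, 189]

principal_events:
  intervention:
    probabilities:
      acute_myocardial_infarction: 0.0      # printed "<0.00000001"
      pulmonary_embolism: 0.00006559
      acute_pulmonary_oedema: 0.00004368
      respiratory_failure: 0.0
      severe_sepsis: 0.00000001
      icu_admission: 0.99989071
      cardiopulmonary_arrest: 0.00000001
    concentrations:
      acute_myocardial_infarction: 4.9231e-13
      pulmonary_embolism: 0.0016
      acute_pulmonary_oedema: 0.0011
      respiratory_failure: 3.6014e-13
      severe_sepsis: 3.3553e-07
      icu_admission: 24.3621
      cardiopulmonary_arrest: 1.9882e-07
  control:
    probabilities:
      acute_myocardial_infarction: 0.00000007
      pulmonary_embolism: 0.00012726
      acute_pulmonary_oedema: 0.00002508
      respiratory_failure: 0.00000012
      severe_sepsis: 0.19179070
      icu_admission: 0.74615961
      cardiopulmonary_arrest: 0.06189716
    concentrations:
      acute_myocardial_infarction: 2.9955e-06
      pulmonary_embolism: 0.0051
      acute_pulmonary_oedema: 0.0010
      respiratory_failure: 4.9610e-06
      severe_sepsis: 7.7047
      icu_admission: 29.9749
      cardiopulmonary_arrest: 2.4865

lifetime:
  healthy_qale: 9.7732            # age/sex-matched healthy reference QALE
  life_expectancy_years: 17.74    # model population (age 68, 48% male)
  states:
    ward_gastroenterology:        # "no event", gastroenterology ward component
      lifetime_cost: 28694
      cost_gamma: [25, 1147.75]
      qale: 7.4965
      qale_normal: [7.50, 1.50]
    ward_respiratory:             # "no event", respiratory ward component
      lifetime_cost: 10555
      cost_gamma: [25, 422.19]
      qale: 7.9866
      qale_normal: [7.99, 1.60]
    acute_myocardial_infarction:
      lifetime_cost: 34398
      cost_gamma: [25, 1375.91]
      qale: 6.0139
      qale_normal: [6.01, 1.20]
    pulmonary_embolism:           # no published lifetime cost; the weighted
      carry_forward: true         # no-event cost is carried forward
      qale: 6.9533
      qale_normal: [6.95, 1.39]
    acute_pulmonary_oedema:
      lifetime_cost: 19198
      cost_gamma: [25, 767.92]
      qale: 4.0633
      qale_normal: [4.06, 0.81]
    respiratory_failure:
      lifetime_cost: 19198
      cost_gamma: [25, 767.92]
      qale: 4.0633
      qale_normal: [4.06, 0.81]
    severe_sepsis:
      lifetime_cost: 45903
      cost_gamma: [25, 1836.14]
      qale: 3.3345
      qale_normal: [3.33, 0.67]
    icu_admission:
      lifetime_cost: 19198
      cost_gamma: [25, 767.92]
      qale: 4.0663
      qale_normal: [4.06, 0.81]
    cardiopulmonary_arrest:
      lifetime_cost: 38303
      cost_gamma: [25, 1532.14]
      qale: 3.0013
      qale_normal: [3.00, 0.60]

resource_use:
  beds: 54
  mean_los:
    intervention: 8.62
    control: 8.90
  cableless_rate: 0.123
  product_life: 5
  ward_mix_pulmonology: 0.56      # proportion admitted to the pulmonology ward
  occupancy: 1.0

device_prices:
  fixed_intervention: 77448.61    # IGS + 12 MP5SC spot-check monitors
  sensor_unit: 107.50             # wireless sensor, per unit
  fixed_control: 16800.00         # 12 routine-care spot-check monitors

episode_costs:                    # adjusted mean inpatient episode cost (GBP),
  intervention:                   # gamma GLM with log link; bootstrap 95% CR
    mean: 2046.99
    range: [1926.45, 2183.47]
  control:
    mean: 2059.16
    range: [1957.03, 2174.21]

event_rates:                      # adjusted mean serious adverse events per
  intervention:                   # patient; negative-binomial regression
    mean: 0.0666
    range: [0.0543, 0.0786]
  control:
    mean: 0.0933
    range: [0.0743, 0.1114]

discounting:
  rate: 0.035

# NHS unit costs per episode category (non-elective weighted average and cost
# per excess bed day, GBP 2020/21).  Informational: used by the synthetic
# cohort's cost model, not by the decision engine (episode costs above are
# the adjusted patient-level means).  Stroke and acute renal failure occur as
# episode-cost categories only (zero discharge-state probability).
unit_costs:
  non_elective:
    ward_gastroenterology: 1457
    ward_respiratory: 1641
    acute_myocardial_infarction: 1592
    pulmonary_embolism: 1525
    acute_pulmonary_oedema: 1543
    respiratory_failure: 848
    stroke: 3609
    severe_sepsis: 2385
    acute_renal_failure: 1398
    icu_bed_day: 1620
    cardiopulmonary_arrest: 1628
  excess_bed_day:
    ward_gastroenterology: 259
    ward_respiratory: 230
    acute_myocardial_infarction: 264
    pulmonary_embolism: 230
    acute_pulmonary_oedema: 230
    respiratory_failure: 230
    stroke: 257
    severe_sepsis: 239
    acute_renal_failure: 239
    cardiopulmonary_arrest: 264
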