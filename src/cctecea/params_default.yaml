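# Default parameterization for the South African diabetes CCT microsimulation.
# State economics (annual USD 2020 per person), complication incidence among
# untreated diabetics with multiplicative therapy effects, care-cascade
# utilization probabilities, economic constants, intervention effect, income
# model and the synthetic strata-rate calibration anchors.
#
# Values not available from published sources (income gamma parameters, food
# poverty line, baseline utilization probabilities, strata curve shapes) are
# documented placeholder defaults; see docs/methods.md. All keys overridable.

horizon_years: 45
cycle_length: 1

states:
  healthy:              {direct_medical_cost: 0.0,    oop_cost: 0.0,  disability_weight: 0.0}
  undiagnosed:          {direct_medical_cost: 0.0,    oop_cost: 0.0,  disability_weight: 0.049}
  diagnosed_untreated:  {direct_medical_cost: 23.0,   oop_cost: 13.0, disability_weight: 0.049}
  oral_therapy:         {direct_medical_cost: 185.0,  oop_cost: 51.0, disability_weight: 0.049}
  insulin_therapy:      {direct_medical_cost: 277.0,  oop_cost: 51.0, disability_weight: 0.049}
  combination_therapy:  {direct_medical_cost: 301.0,  oop_cost: 51.0, disability_weight: 0.049}
  nephropathy:          {direct_medical_cost: 1207.0, oop_cost: 90.0, disability_weight: 1.0}
  retinopathy:          {direct_medical_cost: 56.0,   oop_cost: 13.0, disability_weight: 0.184}
  neuropathy:           {direct_medical_cost: 6340.0, oop_cost: 13.0, disability_weight: 0.133}
  angina:               {direct_medical_cost: 16.0,   oop_cost: 13.0, disability_weight: 0.080}
  peripheral_vascular:  {direct_medical_cost: 16.0,   oop_cost: 13.0, disability_weight: 0.014}
  myocardial_infarction: {direct_medical_cost: 1291.0, oop_cost: 90.0, disability_weight: 0.432}
  stroke:               {direct_medical_cost: 2168.0, oop_cost: 90.0, disability_weight: 0.588}
  heart_failure:        {direct_medical_cost: 2493.0, oop_cost: 90.0, disability_weight: 0.179}
  hyperglycaemia:       {direct_medical_cost: 83.0,   oop_cost: 90.0, disability_weight: 0.133}
  hypoglycaemia:        {direct_medical_cost: 76.0,   oop_cost: 90.0, disability_weight: 0.133}
  diabetes_death:       {direct_medical_cost: 0.0,    oop_cost: 0.0,  disability_weight: 1.0}
  other_death:          {direct_medical_cost: 0.0,    oop_cost: 0.0,  disability_weight: 1.0}

# Annual incidence among untreated diabetics; therapy_effect is the
# multiplicative risk ratio applied while on pharmacological treatment.
complications:
  nephropathy:           {untreated_incidence: 0.010,  therapy_effect: 0.30}
  retinopathy:           {untreated_incidence: 0.021,  therapy_effect: 0.68}
  neuropathy:            {untreated_incidence: 0.047,  therapy_effect: 0.94}
  angina:                {untreated_incidence: 0.0067, therapy_effect: 0.68}
  peripheral_vascular:   {untreated_incidence: 0.0085, therapy_effect: 0.74}
  myocardial_infarction: {untreated_incidence: 0.017,  therapy_effect: 0.61}
  stroke:                {untreated_incidence: 0.0053, therapy_effect: 0.59}
  heart_failure:         {untreated_incidence: 0.0033, therapy_effect: 0.68}
  hyperglycaemia:        {untreated_incidence: 0.18,   therapy_effect: 1.0}
  hypoglycaemia:         {untreated_incidence: 0.18,   therapy_effect: 0.68}

# Occupancy of prevalent diabetics across the care cascade at baseline.
# Printed proportions sum to 0.999 and are renormalized on load.
baseline_cascade_split:
  undiagnosed: 0.600
  diagnosed_untreated: 0.007
  oral_therapy: 0.196
  insulin_therapy: 0.036
  combination_therapy: 0.160

cascade:
  p_dx: 0.08            # annual probability an undiagnosed diabetic is diagnosed
  p_dt: 0.30            # probability a newly diagnosed person initiates therapy
  p_tna: 0.25           # annual probability a treated person leaves treatment
  allow_reinitiation: false
  adherence_effect_mode: odds   # 'odds' (OR on adherence = 1 - p_tna) or 'direct'
  treated_mortality_multiplier: 0.25

econ:
  discount_rate: 0.05
  ce_threshold: 3015.0
  che_thresholds: [0.10, 0.25, 0.40]
  food_poverty_line: 120.0        # USD 2020 / year; 40% of Q1 mean income
  cct_diagnosis_amount: 13.0      # one-off transfer per screening/diagnosis visit
  cct_treatment_amount: 51.0      # per adherent treatment-year (4 transfers)
  cct_transfers_per_year: 4
  admin_cost_fraction: 0.0        # scenario value 0.50
  population_per_quintile: 6.0e+6 # represented persons aged 25-69 per quintile
  screening_cct: true             # pay the $13 per screening attendance (see docs)
  discount_dalys: true
  che_net_of_cct: true            # assess CHE on OOP net of transfers received
  che_unit: person_year           # or 'person_ever'

effect:
  odds_ratio: 1.31
  ci_low: 1.12
  ci_high: 1.54
  # Channel-specific overrides used by one-way sensitivity analyses; null
  # means 'use odds_ratio'.
  or_diagnosis: null
  or_treatment: null

income:
  # Annual per-capita income band boundaries, USD 2020 (placeholder defaults).
  quintile_boundaries: [120.0, 480.0, 960.0, 1800.0, 3600.0, 14400.0]
  gamma_shape: 2.0                # per-quintile shape; scale set so mean = band midpoint

population:
  female_share: 0.5
  female_incidence_ratio: 1.3     # female:male diabetes incidence ratio
  age_min: 25
  age_max: 69

calibration:
  # Baseline diabetes prevalence targets by income quintile and the diagnosed
  # share among prevalent diabetics (1 - undiagnosed split).
  prevalence_by_quintile: {1: 0.175, 2: 0.184, 3: 0.195, 4: 0.205, 5: 0.215}
  diagnosed_fraction: 0.40
  tolerance: 0.015

strata:
  synthesize:
    seed: 0
    dm_incidence_base: 0.006      # per year at age 25, pre-calibration
    dm_incidence_slope: 0.05      # exponential age slope per year
    dm_mortality_base: 0.016      # untreated excess mortality at age 25
    dm_mortality_slope: 0.055
    bg_mortality_base: 0.0025     # background mortality at age 25
    bg_mortality_slope: 0.068

psa:
  cost_cv: 0.2
  probability_cv: 0.2
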