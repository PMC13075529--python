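# Base-case parameter set: lifetime cost-effectiveness of ritlecitinib 50 mg
# versus no treatment for alopecia areata with >= 50% scalp hair loss, Japan.
# One provenance comment per entry; all monetary values in JPY.

cohort:
  mean_age: 40.2          # mean age at entry, years (claims-database analysis)
  pct_female: 0.619       # proportion female (claims-database analysis)
  pct_adolescent: 0.074   # aged >=12 to <18; recorded, inert in the dynamics

# Cross-sectional SALT-state occupancy at trial checkpoints (phase 2b/3 trial,
# ritlecitinib 50 mg arm and placebo arm).  Shares sum to 1 per checkpoint.
checkpoints:
  ritlecitinib:
    - week: 12
      shares: {ge50: 0.833, s21_49: 0.103, s11_20: 0.008, le10: 0.056}
    - week: 24
      # printed shares sum to 1.001; rounding residual absorbed into ge50
      shares: {ge50: 0.572, s21_49: 0.194, s11_20: 0.097, le10: 0.137}
    - week: 34            # checkpoint nearest the week-36 cycle boundary
      shares: {ge50: 0.413, s21_49: 0.202, s11_20: 0.119, le10: 0.266}
    - week: 48
      shares: {ge50: 0.364, s21_49: 0.145, s11_20: 0.136, le10: 0.355}
  no_treatment:
    - week: 12
      shares: {ge50: 0.976, s21_49: 0.008, s11_20: 0.008, le10: 0.008}
    - week: 24
      # printed shares sum to 0.999; rounding residual absorbed into ge50
      shares: {ge50: 0.916, s21_49: 0.069, s11_20: 0.0, le10: 0.015}

# Health-state utility weights, TTO vignette valuation (UK general public).
utilities:
  le10: 0.919
  s11_20: 0.853
  s21_49: 0.703
  ge50: 0.554

drug:
  unit_price_jpy: 5584.30  # NHI drug price per 50 mg daily dose (2025 revision)
  adherence: 0.974         # treatment adherence, ritlecitinib 50 mg (trial CSR)

# Healthcare-resource-utilisation costs per month, by SALT stratum
# (claims-database analysis; 11-20 and 21-49 back-calculated, hence equal).
hcru_monthly_jpy:
  ge50:   {drug: 3233, non_drug: 13783}
  s21_49: {drug: 3082, non_drug: 7967}
  s11_20: {drug: 3082, non_drug: 7967}
  le10:   {drug: 1558, non_drug: 7730}

# Adverse events occurring in >= 5% of trial patients; incidences are
# cumulative (48 weeks on ritlecitinib, 24 weeks untreated); management cost
# per event from expert opinion.
adverse_events:
  - {name: acne,                incidence_treated: 0.092, incidence_untreated: 0.046, unit_cost_jpy: 625}
  - {name: constipation,        incidence_treated: 0.008, incidence_untreated: 0.0,   unit_cost_jpy: 25}
  - {name: diarrhea,            incidence_treated: 0.092, incidence_untreated: 0.038, unit_cost_jpy: 84}
  - {name: dizziness,           incidence_treated: 0.031, incidence_untreated: 0.008, unit_cost_jpy: 0}
  - {name: folliculitis,        incidence_treated: 0.062, incidence_untreated: 0.023, unit_cost_jpy: 505}
  - {name: headache,            incidence_treated: 0.123, incidence_untreated: 0.084, unit_cost_jpy: 68}
  - {name: nasopharyngitis,     incidence_treated: 0.138, incidence_untreated: 0.061, unit_cost_jpy: 43}
  - {name: nausea,              incidence_treated: 0.023, incidence_untreated: 0.053, unit_cost_jpy: 3}
  - {name: rash,                incidence_treated: 0.054, incidence_untreated: 0.0,   unit_cost_jpy: 21}
  - {name: urti,                incidence_treated: 0.085, incidence_untreated: 0.076, unit_cost_jpy: 16}
  - {name: urticaria,           incidence_treated: 0.054, incidence_untreated: 0.023, unit_cost_jpy: 237}

# Human-capital productivity-loss inputs (government statistics; WPAI survey
# of the alopecia areata population for absenteeism/presenteeism).
productivity:
  pct_employed: 0.833
  hours_per_week: 36.8
  hourly_wage_jpy: 2353
  impairment:
    ge50:   {absenteeism: 0.015, presenteeism: 0.314}
    s21_49: {absenteeism: 0.005, presenteeism: 0.300}
    s11_20: {absenteeism: 0.005, presenteeism: 0.139}
    le10:   {absenteeism: 0.005, presenteeism: 0.139}

settings:
  cycle_length_weeks: 12          # Markov cycle length
  annual_discount_rate: 0.02      # Japanese HTA guideline rate, costs and QALYs
  cap_age_years: 100.0            # deterministic closure of the lifetime horizon
  wtp_threshold: 5000000.0        # willingness-to-pay, JPY per QALY
  jpy_per_usd: 151.37             # OECD 2024 average exchange rate
  perspective: societal
  discontinuation_cum_48wk: 0.131 # cumulative discontinuation by week 48 (trial)
  weeks_per_year: 52.17857142857143
  worsening_interval_weeks: 52.0  # off-treatment: one SALT category per year
  worsen_new_discontinuers_same_cycle: true
  untreated_worsening_start_week: 48
  ae_cost_recurring: false        # one-off expected AE cost at model start
  wpai_additive: false            # WPAI overall impairment A + (1-A)P
  retirement_age: null            # lifetime accrual of indirect costs
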