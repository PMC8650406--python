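settings:
  arm: ECT
  variant: MAIN
  perspective: SOCIETAL
  start_age: 45
  horizon_years: 35
  cycle_length_days: 30.0
  cycles_per_year: 12
  annual_discount_rate: 0.035
  discount_convention: PER_CYCLE_CONTINUOUS
  half_cycle_correction: false
transitions:
  tpA2B_ect: 0.696
  tpC2B_ect: 0.696
  tpB2C_ect: 0.108
  tpB2C_mect: 0.03
  tpA2B_esk: 0.392
  tpC2B_esk: 0.392
  tpB2C_esk: 0.0724
  tpDepression2Death: 0.00304
  tpD2E: 0.107
  tpE2D: 0.232
  remission_mortality:
    45: 0.00018
    50: 0.000265
    55: 0.000407
    60: 0.000646
    65: 0.001
    70: 0.00163
    75: 0.00285
utilities:
  annual_remission: 0.81
  annual_depression: 0.57
  use_rounded_cycle_values: false
  rounded_cycle_remission: 0.07
  rounded_cycle_depression: 0.05
wages:
  fulltime_wage: 2340.0
  parttime_wage: 680.0
  payroll_tax_rate: 0.12
  payroll_band_low: 702.01
  payroll_band_high: 3863.0
  retirement_age: 65
employment:
  depression_unemployed: 0.54
  depression_parttime: 0.13
  remission_unemployed: 0.23
unit_costs:
  ect_session: 558.0
  esketamine_per_28mg: 163.0
  travel_per_visit: 18.8
  gp_visit: 39.0
  psychiatrist_visit: 176.0
  nurse_administration: 44.0
  antidepressant_cycle: 8.0
  trd_residual_care_cycle: 600.0
  informal_care_depression_cycle: 565.0
  informal_care_remission_cycle: 0.0
  esk_mg_induction: 546.0
  esk_mg_maintenance_month1: 280.0
  esk_mg_maintenance_biweekly: 140.0
state_costs:
  ect/AC:
    societal_lt65: 7932.0
    societal_ge65: 6321.0
    travel_visits: 8
  ect/B_standard:
    societal_lt65: 701.0
    societal_ge65: 118.0
    travel_visits: 0
  ect/B_mect_month1:
    societal_lt65: 3313.0
    societal_ge65: 2730.0
    travel_visits: 4
  ect/B_mect_ongoing:
    societal_lt65: 2161.0
    societal_ge65: 1578.0
    travel_visits: 2
  esk/AC:
    societal_lt65: 7210.0
    societal_ge65: 5599.0
    travel_visits: 8
  esk/B_month1:
    societal_lt65: 2882.0
    societal_ge65: 2299.0
    travel_visits: 4
  esk/B_month2to5:
    societal_lt65: 1583.0
    societal_ge65: 1000.0
    travel_visits: 2
  esk/B_month6:
    societal_lt65: 1890.0
    societal_ge65: 1307.0
    travel_visits: 2
  any/D:
    societal_lt65: 2729.0
    societal_ge65: 1119.0
    travel_visits: 0
  any/EF:
    societal_lt65: 701.0
    societal_ge65: 118.0
    travel_visits: 0
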