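capacity:
  gp_panel: 100.0
  screener_productivity: 4000.0
  screening_interval: 5.0
cost:
  drg_tariff: 8000.0
  gp_cost: 15000.0
  screener_salary: 35000.0
disease:
  discharge_destination: reference_population
  discharge_rate: 36.5
  h2_c: 0.1
  h2_u: 0.35
  incidence_rate: 0.01
  p1_c: 0.05
  p1_u: 0.15
initial_stocks:
  inpatient: 1000.0
  phase1_in_care: 50000.0
  phase1_undetected: 30000.0
  phase2_in_care: 30000.0
  phase2_undetected: 10000.0
  reference_population: 859000.0
policy:
  adjustment_time: 0.25
  adjustment_time_gps: 1.75
  allow_downsizing: true
  fixed_gps: 700.0
  fixed_screeners: 5.0
  kind: fixed
sim:
  dt: 0.08333333333333333
  horizon: 4.0
  stride: 1
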