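# Demo run configuration for the full seven-step workflow.
# All randomness flows from this explicit seed.
seed: 42
provinces: mrd13
historical_years: [1976, 2016]
future_years: [2020, 2050]
baseline_years: [2005, 2016]
scenarios: [RCP4.5, RCP8.5]
# True reduction ratios (D, %) driving the synthetic historical panel.
reduction_truth:
  ElNino: 20.0
  LaNina: 12.0
noise_sd: 0.1
pest_years: [[1992, AW], [2002, AW], [2009, AW]]
pest_depression_pct: 30.0
plots_per_season: {WS: 8, SA: 7, AW: 4}
plot_noise_sd: 0.0
min_years_ef: 5
surrogate:
  potential_yield: 7.0
  t_opt: 28.0
  heat_sensitivity: 0.6
  water_requirement: 400.0
  water_sensitivity: 0.7
  season_length: 100
calibration:
  free: [potential_yield, heat_sensitivity, water_sensitivity]
  bounds:
    potential_yield: [3.0, 12.0]
    heat_sensitivity: [0.0, 2.0]
    water_sensitivity: [0.0, 1.0]
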