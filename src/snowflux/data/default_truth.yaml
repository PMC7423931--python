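# Ground-truth parameter set for the synthetic study generator.
# These defaults define the simulated study conditions: a cold winter
# followed by two warm winters with depleted labile C (lower Q10 intercept A),
# a doubling glucose response, and a first-order labile-pool depletion
# incubation with stronger kinetics at warmer temperatures.
seed: 20190301
field:
  years:
    "2017": {a: 0.8, b: 2.5, soil_temp_range: [-12.0, -3.0]}
    "2018": {a: 0.3, b: 2.5, soil_temp_range: [-6.0, -1.0]}
    "2019": {a: 0.35, b: 2.5, soil_temp_range: [-6.5, -1.0]}
  sigma_ln: 0.2
  glucose_effect: 2.225
  glucose_sigma_ln: 0.25
  pre_flux_median: {hydric: 0.35, mesic: 0.45, xeric: 0.25}
  pre_flux_sigma_ln: 0.4
snow:
  ambient_co2_ppm: 405.0
  sigma_ppm: 10.0
  density_mean: {hydric: 280.0, mesic: 300.0, xeric: 260.0}
  density_sd: 25.0
  temp_mean_c: -6.0
  temp_sd_c: 1.5
  depth_mean_m: 0.6
  depth_sd_m: 0.1
  n_pits_per_site: 3
incubation:
  c_l0_mg_per_g: 0.8          # initial labile C pool, mg C / g dry soil
  k_l_per_day: 0.03           # labile-pool first-order rate constant at 0 degC
  baseline_rate_ug_per_g_day: 2.0   # recalcitrant baseline respiration at 0 degC
  q10: 2.5                    # above-zero temperature sensitivity factor
  lambda_per_degc: 0.12       # extra sub-zero attenuation (liquid-water limitation)
  sigma_jar: 0.2              # jar random-intercept SD (log scale)
  sigma_resid: 0.3            # residual SD (log scale)
# known-coefficient linear scenario for mixed-model parameter recovery:
# ln R = a + bT*T + bC*C + bTC*T*C + bd*date_c + bTd*T*date_c + jar + resid
lmm_scenario:
  intercept: 2.5
  temperature_c: 0.12
  c_addition: 0.5
  temperature_c_x_c_addition: 0.04
  date_c: -0.02
  temperature_c_x_date_c: -0.002
  sigma_jar: 0.2
  sigma_resid: 0.3
nutrients:
  NO3_N:  {alpha: 25.0, beta_temp: 1.0,  beta_c: -6.0, beta_interaction: -0.6,
           sigma: 2.0, log_scale: false}
  NH4_N:  {alpha: 2.5,  beta_temp: 0.05, beta_c: -0.6, beta_interaction: -0.06,
           sigma: 0.3, log_scale: true}
  TFPA:   {alpha: 15.0, beta_temp: 0.3,  beta_c: 4.0,  beta_interaction: 0.4,
           sigma: 2.0, log_scale: false}
  PO4_P:  {alpha: 0.5,  beta_temp: 0.0,  beta_c: 0.0,  beta_interaction: 0.0,
           sigma: 0.1, log_scale: false}
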