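# Default simulation scenario: national-scale dairy test-day recording,
# scaled to ~210,000 records (100 herds x 210 first-lactation cows over
# calving years 2000-2015, 10 weather stations on a north-south gradient).
#
# Per-trait effect sizes are set so the realized response means and
# standard deviations match typical first-lactation Holstein test-day data
# (milk ~27.1 +/- 6.5 kg/day, SCS ~2.33 +/- 1.65), with heat-stress hinge
# terms strong enough that a 0-14 day lag scan at this sample size has
# high power (see docs/methods.md for the variance budget).
n_herds: 100
cows_per_herd: 210
years: [2000, 2015]
n_stations: 10
test_interval_days: 30
test_jitter_days: 5
milk:
  true_lag_days: 3
  bp: 70.4
  slope: -0.3            # kg/day per THI unit above the breakpoint
  herd_sd: 2.5
  year_sd: 0.7
  month_amplitude: -1.0  # kg/day, trough in August
  age_effects: [-0.8, 0.0, 0.8]
  residual_sd: 5.3
  baseline_mean: 27.1
  curve_exp_coef: -5.0   # Wilmink-type rise to a peak near DIM 45
  curve_exp_rate: 0.05
  curve_linear: -0.03    # post-peak decline, kg/day per DIM
scs:
  true_lag_days: 8
  bp: 68.5
  slope: 0.08            # score units per THI unit above the breakpoint
  herd_sd: 0.5
  year_sd: 0.15
  month_amplitude: 0.25  # score units, peak in August
  age_effects: [-0.15, 0.0, 0.15]
  residual_sd: 1.52
  baseline_mean: 2.33
  curve_exp_coef: 1.2    # elevated fresh-cow SCS
  curve_exp_rate: 0.05
  curve_linear: 0.0035   # late-lactation rise
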