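treatments:
- 0.0
- 0.01
- 0.1
- 1.0
n_per_treatment: 25
horizon: 21
growth:
  '0.0':
    bl_max: 3.252
    k: 0.311
    sigma_length: 0.099
  '0.01':
    bl_max: 3.376
    k: 0.287
    sigma_length: 0.121
  '0.1':
    bl_max: 3.314
    k: 0.299
    sigma_length: 0.111
  '1.0':
    bl_max: 3.339
    k: 0.286
    sigma_length: 0.13
survival:
  '0.0': 0.008
  '0.01': 0.004
  '0.1': 0.004
  '1.0': 0.005
fecundity:
  '0.0': 6.0
  '0.01': 8.9
  '0.1': 9.4
  '1.0': 8.6
fecundity_time_trend: -0.4
maturation_day: 9
interclutch_interval: 3
max_clutches: 4
length_scan_days:
- 3
- 6
microbiome:
  n_otus: 300
  base_sigma: 1.5
  frac_sensitive: 0.45
  slope_sensitive: -5.0
  frac_refractory: 0.1
  slope_refractory: 2.0
  slope_jitter: 0.3
  drift_sigma: 0.15
  theta: 0.02
  depth_mean: 5000.0
  depth_sigma: 0.3
  conc_ref: 0.01
  n_sampled_per_clutch: 4
  frac_unassigned_genus: 0.05
coupling: []
seed: 0
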