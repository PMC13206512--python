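# Default calibration for the lifetime ASCVD microsimulation.
#
# Lipid distribution parameters target the stratum means of the reference
# projection tables; hazard baselines are calibrated toward soft lifetime
# targets (stratum-1 lifetime MI risk ~5% and life expectancy ~80 y,
# stratum-4 lifetime MI risk ~73%, male:female MI ratio ~2 in strata 1-3).
population:
  n_per_stratum: 1000
  sex_split: 0.5
  seed: 0
  ratio_cutoffs: [0.45, 0.35, 0.25]
  ldl_cutoffs: [3.1, 4.0, 5.0]
  lipids:
    "1":
      female: {ratio_mean: 0.63878, ldl_mean: 2.63, tg_mean: 1.10}
      male: {ratio_mean: 0.59289, ldl_mean: 2.53, tg_mean: 1.30}
    "2":
      female: {ratio_mean: 0.39946, ldl_mean: 3.73, tg_mean: 1.40}
      male: {ratio_mean: 0.39535, ldl_mean: 3.44, tg_mean: 1.60}
    "3":
      female: {ratio_mean: 0.30100, ldl_mean: 4.02, tg_mean: 1.70}
      male: {ratio_mean: 0.29771, ldl_mean: 3.93, tg_mean: 1.90}
    "4":
      female: {ratio_mean: 0.22319, ldl_mean: 3.45, tg_mean: 2.00}
      male: {ratio_mean: 0.20904, ldl_mean: 3.54, tg_mean: 2.20}
  prevalence:
    smoker:
      start_age: 15.0
      end_age: 25.0
      max_prev: [0.22, 0.26, 0.30, 0.36]
      sex_factor: {female: 0.85, male: 1.0}
    diabetes:
      start_age: 25.0
      end_age: 80.0
      max_prev: [0.12, 0.16, 0.22, 0.30]
      sex_factor: {female: 0.9, male: 1.0}
    hypertension:
      start_age: 25.0
      end_age: 80.0
      max_prev: [0.40, 0.46, 0.52, 0.60]
      sex_factor: {female: 0.95, male: 1.0}
    atrial_fibrillation:
      start_age: 50.0
      end_age: 85.0
      max_prev: [0.07, 0.08, 0.10, 0.13]
      sex_factor: {female: 0.85, male: 1.0}
  hba1c_mean: {"1": 5.3, "2": 5.5, "3": 5.7, "4": 6.0}
  hba1c_sd: 0.45
  sbp_mean:
    female: {"1": 118.0, "2": 122.0, "3": 126.0, "4": 130.0}
    male: {"1": 122.0, "2": 126.0, "3": 130.0, "4": 134.0}
  sbp_sd: 12.0
  bmi_mean:
    female: {"1": 25.0, "2": 26.0, "3": 27.0, "4": 28.0}
    male: {"1": 26.0, "2": 27.0, "3": 28.0, "4": 29.0}
  bmi_sd: 4.0
  acceptance_floor: 1.0e-3
hazards:
  exposure_threshold: 5000.0
  mi_baseline: {female: 5.6e-7, male: 2.1e-6}
  mi_age_slope: 0.088
  mi_excess_slope: 1.5e-4
  ratio_multiplier: [1.0, 2.05, 5.6, 72.0]
  ihd_baseline: {female: 9.7e-7, male: 1.15e-6}
  ihd_age_slope: 0.088
  stroke_baseline: {female: 6.6e-4, male: 1.05e-3}
  stroke_age_slope: 0.085
  stroke_onset_age: 60.0
  stroke_rr_per_mmol: 0.84
  stroke_ldl_ref: 3.0
  hf_baseline: {female: 1.7e-5, male: 1.6e-5}
  hf_age_slope: 0.075
  gompertz:
    female: [4.2e-4, 3.6e-6, 0.117]
    male: [5.0e-4, 4.5e-6, 0.117]
  case_fatality:
    MI:
      female: [0.440, 0.400, 0.446, 0.407]
      male: [0.474, 0.424, 0.364, 0.354]
    IHD:
      female: [0.890, 0.543, 0.312, 0.139]
      male: [0.776, 0.441, 0.283, 0.240]
    IS:
      female: [0.457, 0.428, 0.484, 0.509]
      male: [0.502, 0.400, 0.423, 0.513]
    HF:
      female: [0.092, 0.119, 0.186, 0.316]
      male: [0.138, 0.158, 0.272, 0.423]
  comorbidity_rr:
    smoker: {MI: 1.6, IHD: 1.5, IS: 1.9, HF: 1.3}
    diabetes: {MI: 1.5, IHD: 1.4, IS: 1.8, HF: 1.8}
    hypertension: {MI: 1.3, IHD: 1.3, IS: 1.6, HF: 1.6}
    atrial_fibrillation: {IS: 2.5, HF: 1.4}
    sbp_per10: {MI: 1.08, IHD: 1.06, IS: 1.15, HF: 1.08}
  sbp_ref: 120.0
  recurrent_multiplier: 1.5
sim:
  time_step: 1.0
  age_cap: 110.0
  seed: 0
utility:
  intercept: {female: 0.945, male: 0.935}
  age_slope: 0.0022
  floor: 0.35
  decrements: {post_mi: 0.88, post_is: 0.85, hf: 0.80, ihd: 0.92, diabetes: 0.95}
  discount_rate: 0.0
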