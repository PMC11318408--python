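# Demo pipeline configuration: a synthetic paired cohort (control aCSF vs
# 3% isoflurane) with the observed median feature values of each condition,
# plus perivascular oxygenation maps for three CMRO2 operating points.
#
# The CMRO2 values below are condition medians reported for acute cortical
# slices (mmHg/s, oxygen partial-pressure equivalents): baseline ~34.4
# rising ~2.7-fold to ~92.0 during a spreading depolarization under aCSF;
# under 3% isoflurane the pre-SD baseline drops to ~34.7 and the SD-evoked
# rise (delta ~18.4) is strongly blunted. They are example inputs, not
# constants of the package.

seed: 20260101

slice_model:
  # chamber supply pO2 at the slice surface (mmHg). Not a universal
  # constant: interface chambers gassed with carbogen commonly sit in the
  # 120-250 mmHg range at the surface; set per rig.
  surface_po2: 150.0
  domain_depth: 160.0      # um, depth of the pO2 minimum (core electrode)
  diffusion_constant: 1600.0
  km: 3.0
  layer_thickness: 1.0

krogh:
  capillary_radius: 2.5    # um lumen radius; 2-4 um plausible, 2.5 reproduces
                           # the 27-um supplied radius at pO2 20 / CMRO2 34.4
  shell_thickness: 0.5
  diffusion_constant: 1600.0
  km: 3.0
  hypoxia_threshold: 8.0

map_grid:
  capillary_po2_min: 20.0
  capillary_po2_max: 55.0
  capillary_po2_step: 5.0
  radius_min: 10.0
  radius_max: 35.0
  radius_step: 1.0

map_scenarios:
  acsf:             {baseline_cmro2: 34.4, sd_cmro2: 92.0}
  isoflurane_1pct:  {baseline_cmro2: 38.9, sd_cmro2: 78.3}   # 38.9 + 39.4
  isoflurane_3pct:  {baseline_cmro2: 34.7, sd_cmro2: 53.1}   # 34.7 + 18.4

episode:             # control (aCSF) episode medians
  baseline_cmro2: 34.4
  peak_ratio: 2.7
  dc_duration: 43.0
  delta_k: 22.6
  t1_50: 20.0
  t2_50: 65.0
  onset: 60.0
  sampling_rate: 10.0

treated_episode:     # 3% isoflurane episode medians
  baseline_cmro2: 34.7
  peak_ratio: 1.53   # (34.7 + 18.4) / 34.7
  dc_duration: 107.0
  delta_k: 16.5
  t1_50: 38.3
  t2_50: 235.7
  onset: 60.0
  sampling_rate: 10.0

cohort:
  n_slices: 12
  slice_effect_sd: 0.3
  episode_effect_sd: 0.1
  synthesize: false        # fast feature-level cohort; true = full traces
  depths: [40.0, 100.0, 160.0]
  duration_s: 420.0

fit:
  smoothing_window_s: 1.0
  baseline_window: [0.0, 55.0]
  stride: 5
  bounds: [0.0, 500.0]
  xtol: 0.001
  profile_noise_sd: 1.0
  auc_horizon_s: 300.0

stats:
  m_comparisons: 2         # each isoflurane level vs control, not vs each other
  method: auto
  features: [delta_k, dc_duration, t1_50, t2_50]
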