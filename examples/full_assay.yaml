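# Full simulated assay: bacterial dose series (6 doses + NC + 2 uM PC),
# RBC dose series (6 doses + NC + osmotic PC) and mixed bacteria+RBC samples,
# at the nominal concentrations (2e5 beads, 4e5 bacteria, 3e5 RBC per mL).
# All values shown are the package defaults; edit freely.
# Run with:  ampcyt run-all -c examples/full_assay.yaml
seed: 1
output_dir: ampcyt_run
duration_s: 5.0
acquisition:
  frequencies:
  - 500000.0
  - 11000000.0
  - 20000000.0
  sampling_rate: 115000.0
  electrode_width_um: 30.0
  electrode_gap_um: 10.0
  channel_width_um: 40.0
  channel_height_um: 20.0
  flow_rate_ul_min: 10.0
  noise_rms: 0.5
  position_blur_rel_sd: 0.15
  position_phase_sd: 0.03
  gain: 1.0
  velocity_rel_sd: 0.05
medium:
  conductivity: 1.3
  relative_permittivity: 80.0
dose_model:
  k_kill_um: 0.034
  n_kill: 2.7
  k_lysis_um: 0.15
  n_lysis: 1.5
  accumulation_slope: 0.25
detection:
  threshold_k: 6.0
  min_separation_s: 0.0008
  window_halfwidth_s: 0.0006
gate:
  bacteria_rbc_threshold_um: 3.8
  sizing_frequency: 500000.0
  hl_split_frequency: 20000000.0
  hl_method: two_component_mixture
  hl_fixed_threshold: -0.5
max_residual: 0.3
min_beads: 10
bead_concentration: 200000.0
bacteria_concentration: 400000.0
rbc_concentration: 300000.0
bacteria_doses:
- 0.025
- 0.05
- 0.1
- 0.2
- 0.4
- 0.8
bacteria_pc_dose: 2.0
rbc_doses:
- 0.025
- 0.05
- 0.1
- 0.2
- 0.4
- 0.8
mixed_doses:
- 0.0
- 0.35
run_bacteria: true
run_rbc: true
run_mixed: true
cfu_nc: 200
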