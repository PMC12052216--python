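units:
  pixel_size_um: 3.0
  seconds_per_mcs: 27.0
  reference_displacement_um_per_mcs: 0.3
  reference_speed_um_per_h: 40.0
grid:
  width: 200
  height: 200
  wound_size: 120
  cell_size: 8
  macrophage_count: 30
  preexisting_count: 12
  preexisting_inf_value: 0.08
  wound_csf1_init: 0.15
energy:
  temperature: 4.2
  contact:
  - - 0.0
    - 8.0
    - 8.0
    - 8.0
    - 8.0
    - 8.0
    - 4.0
  - - 8.0
    - 11.0
    - 11.0
    - 11.0
    - 11.0
    - 11.0
    - 6.0
  - - 8.0
    - 11.0
    - 11.0
    - 11.0
    - 11.0
    - 11.0
    - 6.0
  - - 8.0
    - 11.0
    - 11.0
    - 11.0
    - 11.0
    - 11.0
    - 6.0
  - - 8.0
    - 11.0
    - 11.0
    - 11.0
    - 11.0
    - 11.0
    - 6.0
  - - 8.0
    - 11.0
    - 11.0
    - 11.0
    - 11.0
    - 11.0
    - 6.0
  - - 4.0
    - 6.0
    - 6.0
    - 6.0
    - 6.0
    - 6.0
    - 2.0
  lambda_volume:
  - 0.0
  - 2.0
  - 2.0
  - 2.0
  - 2.0
  - 2.0
  - 500.0
  target_volume:
  - 0.0
  - 64.0
  - 64.0
  - 64.0
  - 64.0
  - 64.0
  - 1.0
  lambda_surface:
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  target_surface:
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  chem_field:
  - -1
  - 0
  - 0
  - 3
  - -1
  - -1
  - -1
  chem_lambda:
  - 0.0
  - 1000.0
  - 1000.0
  - 1500.0
  - 0.0
  - 0.0
  - 0.0
  chem_lambda_ecm:
  - 0.0
  - 2000.0
  - 2000.0
  - 1500.0
  - 0.0
  - 0.0
  - 0.0
  contact_order: 2
  copy_order: 1
fields:
  diffusion:
  - 0.2
  - 0.2
  - 0.2
  - 0.2
  decay:
  - 0.001
  - 0.0005
  - 0.001
  - 0.001
  secretion:
    mac_pdgf: 0.03
    mac_mmp: 0.01
    fib_csf1: 0.015
    myo_pdgf: 0.01
    myo_csf1: 0.015
    sen_pdgf: 0.02
    sen_csf1: 0.008
    sen_inf: 0.01
    sen_mmp: 0.007
  substeps: 0
behavior:
  gmax_f: 0.025
  gmax_mf: 0.03
  gmax_m: 0.011
  pdgf0: 0.02
  csf0: 0.015
  t_ci: 0.08
  p_mf: 0.1
  p_snc: 0.15
  p_clear: 0.05
  t_sen: 12.0
  t_sen_mode: open_after
  t_nis_days: 3.0
  pdgf_f: 0.01
  snc_thr: 0.03
  mmp_thr: 0.03
  ecm_thr: 3.0
  inf_thr: 0.02
  csf1_thr: 0.002
  mu_per_day: 0.05
  ecm_fib: 2
  ecm_myof: 4
  sweep_period_mcs: 500
  fate_period_mcs: 2000
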