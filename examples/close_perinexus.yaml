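geometry:
  R_ID: 11.0
  L: 100.0
  Lx: 300.0
  Ly: 55.0
  Lz: 55.0
  r_Na: 0.6875
  r_GJ: 0.6875
  r_peri: 2.26875
  patch_radius: 2.0
  patch_offset: 10.0
layout:
  configuration: close
  w_cleft: 50.0
  w_peri: 10.0
  w_plaque: 2.0
  f_sigma_plaque: 0.1
  has_perinexus: true
  exclude_cluster_from_gap: true
solver:
  alpha: 0.5
  beta: 0.5
  dt: 0.0005
  duration: 10.0
  output_stride: 20
  v_rest: -85.0
  stop_margin: 2.5
  stop_on_quiescence: true
conductivities:
  sigma_i: 3.333
  sigma_e: 6.666
  sigma_cleft: 6.666
membrane:
  gbar_Na: 23.0
  gbar_K: 0.3
  E_Na: 55.0
  E_K: -85.0
  C_m: 1.0
stimuli:
- cell: 1
  mode: current_clamp
  amplitude: 11.5
  onset: 0.0
  duration: 0.5
G_gap_fraction: 0.0
G_gap_absolute: null
junctional_resistivity: 1.5
P: 0.5
snapshot_times: []
resolution: coarse
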