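# Shipped default configuration.
#
# Structural ranges are free parameters calibrated against printed whole-
# lobule statistics (mean vHPCs per lobule, dPV/dCV position fractions and
# band counts); gradient endpoints are calibrated against pericentral-band
# event-timing statistics.  Durations are in simulation cycles (1 cycle =
# 1 s); *_h keys would be converted to cycles on load.

lobule:
  layers:
    - {n_nodes: [44, 52], core_length: [9, 13], circumference: [26, 31]}
    - {n_nodes: [9, 11], core_length: [7, 9], circumference: [6, 7]}
    - {n_nodes: [7, 9], core_length: [8, 10], circumference: [30, 34]}
  hepatocyte_occupancy: 0.90
  ec_occupancy: 0.99
  fanout: [1, 3]
  n_lobules_per_liver: 12

bands:
  pp_dpv: [1, 4]
  mz_dpv: [11, 15]
  pc_dcv: [1, 4]

flow:
  dose_transfer_fraction: 0.005
  downstream_bias: 0.5
  p_enter_cell: 0.1
  p_exit_cell: 0.05
  ec_bind_prob: 0.05
  ec_release_prob: 0.05
  vhpc_bind_prob: 0.05
  vhpc_release_prob: 0.05
  marker_fraction: 0.10

gradients:
  p_metabolism: [[0.0, 0.004], [0.6, 0.015], [0.85, 0.055], [1.0, 0.12]]
  p_napqi: [[0.0, 0.02], [0.45, 0.16], [0.7, 0.35], [0.87, 0.7], [1.0, 0.85]]
  gsh_threshold: [[0.0, 12.0], [0.45, 3.8], [0.7, 3.6], [0.87, 3.0], [1.0, 2.0]]
  p_mitigate_mitod: [[0.0, 0.01], [0.45, 0.0015], [1.0, 0.0005]]
  p_mitigate_nonmd: [[0.0, 0.0005], [1.0, 0.01]]
  p_mito_fraction: 0.5

mechanism:
  release_mode: MITOD
  dual_semantics: sum
  leakage_threshold: 1
  necrosis_threshold: 4
  napqi_removal_prob: 0.5
  amplification_range: [3, 6]
  leak_lag_cycles: [2700, 18000]
  death_delay_cycles: [7200, 21600]
  exlt_shift_cycles: 0
  alt_initial: 5
  futile_cycle: {enabled: false, forward_prob: 0.0, reverse_prob: 0.0}

experiment:
  dose_objects: 50000        # medium dose; maps to 300 mg/kg
  duration_cycles: 21600     # 6 h
  n_trials: 12
  n_lobules: 12
  master_seed: 7
  measure_every: 1
  ledger_check_every: 600
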