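# Default virtual-patient, scenario and controller-profile configuration.
# Units: pressures mmHg, times s (unless suffixed _min), rates mL/min.

plant:
  lag_time: 15.0             # s, dose-change to pressure-response delay
  responsiveness_tau: 60.0   # s, first-order rise time constant
  overshoot_frac: 0.10       # fractional transient peak above steady state
  overshoot_tau: 120.0       # s, overshoot transient decay
  max_effect: 60.0           # mmHg, dose-response asymptote
  half_effect_dose: 1.5      # mL/min, half-effect infusion rate
  hemorrhage_map_slope: 0.03 # mmHg per mL of blood lost
  noise_sd: 0.0              # mmHg s^-1/2; scenarios run noise-free by default
  pulse_amplitude: 0.0

scenario:
  start_maps: [35.0, 45.0, 55.0]
  target_map: 65.0
  duration_min: 30.0
  hemorrhage_rate: 10.0      # mL/min continuous bleed
  controller_tick_s: 10.0    # measurement/decision cadence
  plant_dt_s: 0.25           # integrator step
  seed: 0

controllers:
  pid_aggressive:
    type: pid
    kp: 0.3
    ki: 0.01
    kd: 0.5
    antiwindup_decay: 0.998
    max_rate_step: 0.1
  pid_conservative:
    type: pid
    kp: 0.3
    ki: 0.01
    kd: 0.5
    antiwindup_decay: 0.998
    max_rate_step: 0.05
  stepfis_aggressive:
    type: stepfis
    base_step: 0.035
    cutoff_hz: 0.02
  stepfis_conservative:
    type: stepfis
    base_step: 0.025
    cutoff_hz: 0.02
  anfis_aggressive:
    type: anfis
    safeguard: {gain: 0.08, mult_lo: 0.5, mult_hi: 1.5, dose_max: 6.0}
  anfis_conservative:
    type: anfis
    safeguard: {gain: 0.03, mult_lo: 0.6, mult_hi: 1.15, dose_max: 6.0}
  adrc_aggressive:
    type: adrc
    kp: 0.006
    kd: 0.03
    b: 0.01
    eso_bandwidth: 0.08
    td_speed: 0.02
    max_rate_step: 0.1
  adrc_conservative:
    type: adrc
    kp: 0.003
    kd: 0.08
    b: 0.01
    eso_bandwidth: 0.06
    td_speed: 0.01
    max_rate_step: 0.05
  pfc_aggressive:
    type: pfc
    smooth_window: 5
    dose_increment: 0.5
    threshold_frac: 0.9
    initial_rate: 0.13
  pfc_conservative:
    type: pfc
    smooth_window: 10
    dose_increment: 0.25
    threshold_frac: 0.5
    initial_rate: 0.13
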