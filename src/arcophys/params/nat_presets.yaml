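# Transient Na+ current (I_NaT) parameter presets.
#
# Boltzmann conductance (g_max nS, V_rev mV, V_half mV, k mV) and kinetic
# parameters (tau_a ms, power-law exponent N, tau_h ms) from fits to
# averaged low-Na+ voltage-clamp I-V curves and current time courses of
# adult and 20 dph male finch RA projection neurons at 24 C.
# onset_latency (ms) is the measured delay of the current from the step.
# h_half/h_slope (mV) define the steady-state inactivation curve used when
# the preset is integrated as a gate ODE; they are a calibration choice
# (steady-state inactivation is essentially complete at test potentials,
# window currents <~2% of peak, matching the small recorded persistent
# current).

adult_24C:
  g_max: 174.0
  V_rev: 66.5
  V_half: -44.6
  k: 6.6
  tau_a: 0.10
  N: 10.7
  tau_h: 0.33
  onset_latency: 0.11
  h_half: -80.0
  h_slope: 5.0

juvenile_20dph_24C:
  g_max: 95.0
  V_rev: 60.0
  V_half: -30.7
  k: 7.3
  tau_a: 0.15
  N: 3.7
  tau_h: 0.58
  onset_latency: 0.17
  h_half: -80.0
  h_slope: 5.0
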