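# Synthetic calibrated rate-constant set for the two-particle resurgent
# Na+ channel model (s = activating, f = inactivating particle).
#
# This parameter set is SYNTHETIC: it was calibrated within this package
# (see docs/methods.md) and is not a transcription of any published numeric
# table.  Two values are fixed by the published model description and are
# never refit:
#   * alpha_s exponential-term denominator  K = -1.0 mV
#   * beta_s rate multiplier                A = 0.05 /ms
# The remaining constants were calibrated once so that the simulated
# resurgent protocol peaks at the -45 mV test potential, the decay time
# constant spans ~2-45 ms over -75..-15 mV, and the current is elicited only
# by depolarization followed by repolarization.
#
# Rate-law forms (rates in 1/ms, V in mV):
#   exponential: A * exp((V - V0) / K)
#   linoid:      A * (V - V0) / (exp((V - V0) / K) - 1)
#   sigmoid:     A / (1 + exp((V - V0) / K))

alpha_s: {form: sigmoid, A: 1.0, V0: 0.0, K: -1.0, Q: 1.0}
beta_s: {form: exponential, A: 0.05, V0: -30.0, K: -21.64, Q: 1.0}
alpha_f: {form: sigmoid, A: 0.3, V0: -30.0, K: 6.0, Q: 1.0}
beta_f: {form: sigmoid, A: 0.3, V0: -30.0, K: -6.0, Q: 1.0}

g_NaR: 0.0112   # uS; adult-calibrated default (peak I_NaR/I_NaT ~ 0.28)
E_NaR: 67.0     # mV
dt: 0.03        # ms, Euler integration step
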