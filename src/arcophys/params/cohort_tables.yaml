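# Per-group statistics (mean, SEM, N) of passive and spontaneously active
# properties of arcopallial neurons, used by the synthetic cohort generator.
# Groups: age (days post hatch) x sex at ~24 C unless noted; "outside"
# denotes arcopallial neurons outside nucleus RA.
#
# Units: r_in MOhm, tau_m ms, c_m pF, spont_freq Hz, threshold mV, hw ms,
# amp mV, max_depol V/s, max_repol V/s.
#
# Notes:
# * the adult_male_40C group has no printed passive values; it borrows the
#   adult_male_24C passive rows (flagged as an extrapolation) with kinetics
#   understood as Q10-scaled.
# * female groups print no tau_m/c_m rows; a nominal c_m is assigned for
#   simulation only and is not a recovery target (recover: false).
# * the adult_male_24C half-width SEM is read as 2.1e-2 ms, consistent with
#   the neighbouring ages' SEM scale.

juvenile_20dph_male_24C:
  channel_preset: juvenile_20dph_24C
  r_in: {mean: 422.0, sem: 32.7, n: 16}
  tau_m: {mean: 39.0, sem: 2.8, n: 15}
  c_m: {mean: 103.3, sem: 15.8, n: 15}
  spont_freq: {mean: 5.7, sem: 0.7, n: 14}
  threshold: {mean: -43.7, sem: 0.8, n: 13}
  hw: {mean: 1.8, sem: 0.07, n: 13}
  amp: {mean: 85.1, sem: 1.0, n: 13}
  max_depol: {mean: 260.0, sem: 15.1, n: 13}
  max_repol: {mean: 42.8, sem: 2.7, n: 13}

male_35dph_24C:
  channel_preset: juvenile_20dph_24C
  r_in: {mean: 285.4, sem: 19.9, n: 18}
  tau_m: {mean: 28.0, sem: 3.5, n: 17}
  c_m: {mean: 109.0, sem: 17.4, n: 17}
  spont_freq: {mean: 5.0, sem: 1.4, n: 17}
  threshold: {mean: -48.1, sem: 1.5, n: 16}
  hw: {mean: 1.2, sem: 0.08, n: 16}
  amp: {mean: 88.6, sem: 1.6, n: 16}
  max_depol: {mean: 364.8, sem: 20.6, n: 16}
  max_repol: {mean: 77.9, sem: 4.8, n: 16}

male_50dph_24C:
  channel_preset: adult_24C
  r_in: {mean: 175.7, sem: 17.6, n: 19}
  tau_m: {mean: 25.9, sem: 3.0, n: 15}
  c_m: {mean: 155.6, sem: 19.5, n: 15}
  spont_freq: {mean: 6.8, sem: 1.0, n: 17}
  threshold: {mean: -48.3, sem: 0.7, n: 17}
  hw: {mean: 0.8, sem: 0.05, n: 17}
  amp: {mean: 90.0, sem: 1.8, n: 17}
  max_depol: {mean: 488.8, sem: 22.1, n: 17}
  max_repol: {mean: 130.4, sem: 7.6, n: 17}

adult_male_24C:
  channel_preset: adult_24C
  r_in: {mean: 190.2, sem: 25.4, n: 14}
  tau_m: {mean: 18.8, sem: 1.7, n: 11}
  c_m: {mean: 114.3, sem: 15.3, n: 11}
  spont_freq: {mean: 9.2, sem: 2.5, n: 17}
  threshold: {mean: -54.0, sem: 2.0, n: 14}
  hw: {mean: 0.6, sem: 0.021, n: 14}
  amp: {mean: 90.5, sem: 1.9, n: 14}
  max_depol: {mean: 534.5, sem: 33.6, n: 14}
  max_repol: {mean: 181.9, sem: 10.2, n: 14}

adult_male_40C:
  channel_preset: adult_24C
  extrapolated_passive: true
  r_in: {mean: 190.2, sem: 25.4, n: 14, recover: false}
  tau_m: {mean: 18.8, sem: 1.7, n: 11, recover: false}
  c_m: {mean: 114.3, sem: 15.3, n: 11, recover: false}
  spont_freq: {mean: 45.0, sem: 10.3, n: 8}
  threshold: {mean: -44.1, sem: 0.7, n: 8}
  hw: {mean: 0.18, sem: 0.02, n: 8}
  amp: {mean: 62.7, sem: 3.0, n: 8}
  max_depol: {mean: 592.4, sem: 66.5, n: 8}
  max_repol: {mean: 478.9, sem: 63.5, n: 8}

adult_male_outside_24C:
  channel_preset: juvenile_20dph_24C
  r_in: {mean: 276.0, sem: 36.8, n: 12}
  tau_m: {mean: 47.5, sem: 4.0, n: 12}
  c_m: {mean: 195.6, sem: 23.3, n: 12}
  spont_freq: {mean: 6.5, sem: 2.5, n: 4}
  threshold: {mean: -38.3, sem: 0.4, n: 4}
  hw: {mean: 2.1, sem: 0.2, n: 4}
  amp: {mean: 62.3, sem: 8.0, n: 4}
  max_depol: {mean: 144.0, sem: 30.8, n: 4}
  max_repol: {mean: 41.1, sem: 8.2, n: 4}

female_20dph_24C:
  channel_preset: juvenile_20dph_24C
  r_in: {mean: 442.3, sem: 34.2, n: 19}
  c_m: {mean: 100.0, sem: 0.0, n: 1, recover: false}
  spont_freq: {mean: 2.5, sem: 0.7, n: 11}
  threshold: {mean: -46.5, sem: 1.8, n: 11}
  hw: {mean: 1.7, sem: 0.07, n: 11}
  amp: {mean: 88.2, sem: 2.6, n: 11}
  max_depol: {mean: 247.5, sem: 12.2, n: 11}
  max_repol: {mean: 49.7, sem: 2.5, n: 11}

female_35dph_24C:
  channel_preset: juvenile_20dph_24C
  r_in: {mean: 255.1, sem: 26.2, n: 24}
  c_m: {mean: 100.0, sem: 0.0, n: 1, recover: false}
  spont_freq: {mean: 4.7, sem: 1.5, n: 10}
  threshold: {mean: -44.1, sem: 1.0, n: 10}
  hw: {mean: 1.6, sem: 0.09, n: 10}
  amp: {mean: 78.5, sem: 2.9, n: 10}
  max_depol: {mean: 210.1, sem: 19.6, n: 10}
  max_repol: {mean: 52.0, sem: 4.8, n: 10}

female_50dph_24C:
  channel_preset: juvenile_20dph_24C
  r_in: {mean: 262.6, sem: 22.5, n: 8}
  c_m: {mean: 100.0, sem: 0.0, n: 1, recover: false}
  spont_freq: {mean: 5.3, sem: 2.1, n: 3}
  threshold: {mean: -47.9, sem: 0.8, n: 3}
  hw: {mean: 1.5, sem: 0.2, n: 3}
  amp: {mean: 78.9, sem: 1.9, n: 3}
  max_depol: {mean: 255.8, sem: 29.9, n: 3}
  max_repol: {mean: 63.6, sem: 11.5, n: 3}
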