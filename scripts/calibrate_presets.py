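#!/usr/bin/env python
"""Calibration harness for the shipped presets.

Re-evaluates, in one place, every calibration anchor behind the shipped
parameter files and prints the realized values next to their targets and
tolerances.  Run after touching any preset:

    python scripts/calibrate_presets.py

Anchors (targets in parentheses):
  * resurgent I-V peak test level (-45 mV) and adult peak I_NaR/I_NaT (0.28)
  * juvenile normalized resurgent current (< 0.05 at all levels)
  * decay tau envelope over -75..-15 mV (within 2-45 ms, monotone)
  * surrogate evoked spike features (within +/-30% of group means, with the
    documented exceptions; see docs/methods.md)
  * adult passive sag at -150 pA (~5 mV)
  * dynamic clamp: juvenile add-mode mean dIFF across the four printed
    conductances (15-20%), adult subtract-mode dIFF < 0 at >= 1.0 units
"""

from dataclasses import replace

import numpy as np


def main():
    from arcophys.ap import (detect_spikes, passive_props, spike_features,
                             train_metrics)
    from arcophys.dynclamp import compare_on_off, neuron_preset, simulate_neuron
    from arcophys.presets import (G_NAR_JUVENILE, nat_gate_kinetics,
                                  resurgent_channel)
    from arcophys.sweeps import resurgent_protocol
    from arcophys.vc import fit_exp_decay, measure_iv, run_resurgent_protocol

    proto = resurgent_protocol(dt=0.03)
    print("== resurgent channel ==")
    ss = run_resurgent_protocol(resurgent=resurgent_channel(),
                                nat=nat_gate_kinetics("adult_24C"),
                                protocol=proto)
    iv = measure_iv(ss)
    i45 = int(np.argwhere(iv.V == -45.0)[0][0])
    print(f"peak level: {iv.peak_level} mV (target -45)")
    print(f"adult I_NaR/I_NaT at -45: {iv.I_norm[i45]:.3f} (target 0.28)")
    for sw in ss:
        lvl = sw.meta["test_level"]
        if not (-75.0 <= lvl <= -15.0):
            continue
        w = sw.window(sw.meta["test_onset"] + 0.5, sw.t[-1])
        seg_t, seg_y = sw.t[w], sw.y[w]
        i_pk = int(np.argmin(seg_y))
        fit = fit_exp_decay(seg_t[i_pk:], seg_y[i_pk:])
        print(f"decay tau at {lvl:+.0f} mV: {fit['tau']:.1f} ms (envelope 2-45)")
    ssj = run_resurgent_protocol(
        resurgent=resurgent_channel(g_NaR=G_NAR_JUVENILE),
        nat=nat_gate_kinetics("juvenile_20dph_24C"), protocol=proto)
    print(f"juvenile max I_norm: {measure_iv(ssj).I_norm.max():.3f} (< 0.05)")

    print("\n== surrogate neurons (evoked features, +/-30% targets) ==")
    targets = {
        "adult": dict(amp=500.0, thr=-54.0, a=90.5, hw=0.6, d=534.5, r=181.9),
        "juvenile_20dph": dict(amp=300.0, thr=-43.7, a=85.1, hw=1.8, d=260.0,
                               r=42.8),
    }
    for name, tg in targets.items():
        sw = simulate_neuron(neuron_preset(name), step_pA=tg["amp"],
                             duration=700.0, step_duration=500.0)
        times = detect_spikes(sw)
        times = times[times >= 100.0]   # skip the settling transient
        f = spike_features(sw, times[0])
        tm = train_metrics(sw, (100.0, 600.0))
        print(f"{name}: thr {f.threshold:.1f} ({tg['thr']}), "
              f"amp {f.amplitude:.1f} ({tg['a']}), hw {f.half_width:.2f} "
              f"({tg['hw']}), maxD {f.max_depol_rate:.0f} ({tg['d']}), "
              f"maxR {f.max_repol_rate:.0f} ({tg['r']}), "
              f"amp ratio last/first {tm.amplitude_ratio_last_first}")

    p = replace(neuron_preset("adult"), g_na=0.0, g_k=0.0)
    sw = simulate_neuron(p, step_pA=-150.0, duration=1000.0, step_onset=200.0,
                         step_duration=600.0)
    pp = passive_props(sw, -150.0, (200.0, 800.0))
    print(f"adult passive sag: {pp.sag:.2f} mV (target ~5.0)")

    print("\n== dynamic clamp ==")
    ch = resurgent_channel()
    rep = compare_on_off(neuron_preset("juvenile_20dph"), ch,
                         [0.1, 0.15, 0.2, 0.25], mode="add", step_pA=300.0)
    d = [r["delta_iff_pct"] for r in rep]
    print(f"juvenile add dIFF%: {np.round(d, 1)} mean {np.mean(d):.1f} "
          "(band 15-20)")
    rep2 = compare_on_off(neuron_preset("adult"), ch, [0.25, 0.5, 1.0, 1.5],
                          mode="subtract", step_pA=300.0)
    print("adult subtract (g, dIFF%, dAHP mV):",
          [(r["g_printed"], round(r["delta_iff_pct"], 1),
            round(r["delta_ahp"], 2)) for r in rep2])


if __name__ == "__main__":
    main()
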