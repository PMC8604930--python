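# arcophys

Modelling and analysis tools for the intrinsic excitability of songbird
arcopallial projection neurons — the ultrafast-spiking upper motor neurons
of the zebra finch song nucleus RA, functional analogs of layer-5
pyramidal neurons in mammalian motor cortex.  The scientific focus is the
**resurgent sodium current** (I_NaR): an inward Na⁺ current that flows on
repolarization after a depolarizing step, as open-channel-blocked channels
transiently re-open.  I_NaR keeps Na⁺ channels available during
high-frequency firing and is a key ingredient of these neurons'
sub-millisecond spikes.

## What the package does

* **Resurgent current model** (`arcophys.gating`) — a Hodgkin–Huxley-type
  conductance gated by an activating particle *s* and an inactivating
  particle *f*,

  ```
  I_NaR = g_NaR · s · f · (V − E_NaR),   τ_x = 1/(α_x+β_x),  x∞ = α_x·τ_x
  ```

  integrated by forward Euler at 0.03 ms, usable both as a simulated
  channel and as the dynamic-clamp current source.  The shipped rate
  constants are a calibrated synthetic set (see `docs/methods.md`).
* **Transient Na⁺ current** (`arcophys.nat`) — Boltzmann conductance
  I(V) = g_max(V−V_rev)/(1+exp((V_half−V)/k)), power-law activation
  (1−e^(−t/τ_a))^N and single-exponential inactivation, with adult and
  juvenile presets from fits to finch recordings.
* **Voltage-clamp toolchain** (`arcophys.vc`) — the resurgent protocol
  (hold −90 mV, condition +30 mV × 10 ms, test +15…−75 mV), peak I–V and
  I_NaR/I_NaT normalization, exponential decay fits, onset-latency
  detection, P/4 leak subtraction, Boltzmann and power-law fits.
* **Current-clamp analysis** (`arcophys.ap`) — spike detection, threshold
  (10 V/s criterion), amplitude, half-width, maximum
  depolarization/repolarization rates, AHP, phase-plane trajectories,
  train metrics (spikes/s, instantaneous firing frequency, adaptation
  ratios), membrane-potential residence distributions, passive properties
  (R_in, τ_m, C_m = 10³·τ_m/R_in, sag) and the capacitive peak-current
  estimate I = C_m · max dV/dt.
* **In-silico dynamic clamp** (`arcophys.dynclamp`) — a calibrated
  single-compartment surrogate neuron (juvenile and adult presets) and a
  closed loop that adds or subtracts the modelled I_NaR every 0.03 ms.
* **Synthetic cohorts** (`arcophys.cohort`) — cells drawn from the
  published group statistics (mean ± SEM, N) and rendered as analytic
  spike trains, passive responses and raw voltage-clamp families, so the
  whole analysis pipeline is testable against known ground truth.

## Worked example

```python
import numpy as np
from arcophys.presets import resurgent_channel, nat_gate_kinetics
from arcophys.sweeps import resurgent_protocol
from arcophys.vc import run_resurgent_protocol, measure_iv
from arcophys.ap import estimate_peak_ina

sweeps = run_resurgent_protocol(resurgent=resurgent_channel(),
                                nat=nat_gate_kinetics("adult_24C"),
                                protocol=resurgent_protocol(dt=0.03))
iv = measure_iv(sweeps)
print("peak I_NaR at", iv.peak_level, "mV")
print("I_NaR/I_NaT:", np.round(iv.I_norm, 3))
print("peak Na+ current:", estimate_peak_ina(114.3, 534.5), "nA")
```

prints

```
peak I_NaR at -45.0 mV
I_NaR/I_NaT: [0.202 0.252 0.279 0.169 0.028 0.016 0.012]
peak Na+ current: 61.09335 nA
```

i.e. the modelled resurgent current is largest at the −45 mV test
potential (the ratios run −75 → +15 mV), its adult normalized peak is
0.28 of the transient current, and an adult cell's capacitance times its
maximal upstroke slope implies a ~61 nA peak Na⁺ current during the
action-potential upstroke.

The command line exposes the same pipeline:

```
arcophys simulate-vc --preset adult_24C --out vc/ --seed 1
arcophys analyze-vc --in vc/ --report iv.csv
arcophys synth-cohort --group adult_male_24C --n 20 --seed 7 --out cohort/
arcophys analyze-cc --in cohort/cc --features spikes.csv
arcophys dynclamp --preset juvenile_20dph --mode add --g 0.1,0.15,0.2,0.25 \
    --stim 300pA:1s --report pairs.csv
```

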